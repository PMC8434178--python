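"""Applicability index for orphan-target screening.

Whether chemogenomic screening will work on a ligand-less target depends on
how much ligand knowledge exists for related targets.  The applicability
index aggregates it as A(p_i) = Σ_j w(K_P(p_i, p_j)) · N_j, summing each
neighbor target's active-ligand count N_j weighted by a sigmoid
w(x) = 1 / (1 + exp(-α(x - r))) of the protein-kernel similarity.  The
sigmoid parameters (α, r) are fitted to maximize the Spearman correlation
between log A (natural log) and observed screening AUROC across benchmark
targets; a threshold on log A is then chosen to maximize the accuracy of
predicting which targets reach an AUROC cutoff (default 0.8), and the
prediction quality is reported as PPV, accuracy and a Fisher exact p-value.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.special import expit

from .exceptions import DataError

__all__ = [
    "ApplicabilityParams",
    "ApplicabilityResult",
    "ApplicabilityClassifier",
    "ClassificationReport",
    "weight",
    "applicability_index",
    "spearman",
    "fit_weight_params",
    "select_threshold",
    "classification_report",
]


@dataclass
class ApplicabilityParams:
    """Sigmoid weight parameters: steepness alpha > 0, midpoint r."""

    alpha: float
    r: float

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise DataError("alpha must be positive")


@dataclass
class ApplicabilityResult:
    target_id: str
    A: float
    logA: float  # natural log; -inf sentinel when A == 0
    neighbor_contributions: list[tuple[str, float, float, float]]
    # (protein_id, KP value, Nj, weighted contribution)


@dataclass
class ClassificationReport:
    tp: int
    fp: int
    tn: int
    fn: int
    ppv: float  # nan when no predicted positives
    accuracy: float
    fisher_p: float
    ppv_defined: bool = True


@dataclass
class ApplicabilityClassifier:
    """Fitted weight parameters plus the log A decision threshold.

    Targets with logA >= threshold are predicted applicable (expected to
    reach the AUROC cutoff when screened as orphans).
    """

    params: ApplicabilityParams
    threshold_logA: float
    auroc_cutoff: float = 0.8
    fit_spearman_: Optional[float] = None
    fit_accuracy_: Optional[float] = None

    def predict(self, logA: Sequence[float]) -> np.ndarray:
        return np.asarray(logA, float) >= self.threshold_logA


# ---------------------------------------------------------------------------


def weight(x, params: ApplicabilityParams):
    """Sigmoid weight w(x) = 1 / (1 + exp(-alpha (x - r))), in (0, 1)."""
    return expit(params.alpha * (np.asarray(x, float) - params.r))


def applicability_index(
    target_id: str,
    neighbors: Sequence[tuple[str, float, float]],
    params: ApplicabilityParams,
) -> ApplicabilityResult:
    """A = Σ_j w(KP_j) · N_j over neighbor targets (the target itself must
    not appear: its own ligand count is unknown for a true orphan).

    Returns logA = ln(A), or a -inf sentinel with a warning when A = 0.
    """
    contribs = []
    A = 0.0
    for pid, kp, nj in neighbors:
        if pid == target_id:
            raise DataError("the target itself must be excluded from its neighbors")
        if nj < 0:
            raise DataError("active-ligand counts must be non-negative")
        c = float(weight(kp, params)) * float(nj)
        contribs.append((pid, float(kp), float(nj), c))
        A += c
    if A > 0:
        logA = math.log(A)
    else:
        warnings.warn(f"applicability index of {target_id!r} is 0; logA undefined")
        logA = float("-inf")
    return ApplicabilityResult(target_id, A, logA, contribs)


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson on mid-ranks, ties averaged)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise DataError("spearman needs two equal-length vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DataError("spearman undefined for constant input")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


# ---------------------------------------------------------------------------
# parameter fitting


def _log_index_vector(
    KP_rows: Sequence[Sequence[tuple[str, float, float]]],
    alpha: float,
    r: float,
) -> np.ndarray:
    out = np.empty(len(KP_rows))
    for i, row in enumerate(KP_rows):
        kp = np.array([v[1] for v in row], float)
        nj = np.array([v[2] for v in row], float)
        A = float(expit(alpha * (kp - r)) @ nj)
        out[i] = math.log(A) if A > 0 else -np.inf
    return out


def fit_weight_params(
    aurocs: Sequence[float],
    KP_rows: Sequence[Sequence[tuple[str, float, float]]],
    alpha_bounds: tuple[float, float] = (0.1, 200.0),
    r_bounds: tuple[float, float] = (0.0, 1.0),
    coarse: int = 25,
    refine_rounds: int = 3,
    refine_grid: int = 15,
    seed: int = 0,
) -> tuple[ApplicabilityParams, float]:
    """Fit (alpha, r) maximizing Spearman(auroc, logA) over bounded ranges.

    A deterministic coarse grid (alpha geometric, r linear) is scanned first
    and then refined by successive zoomed grids around the best point, so
    the returned objective is never below the best coarse-grid value and
    the result is reproducible.  Returns the fitted parameters and the
    achieved correlation.
    """
    aurocs = np.asarray(aurocs, float)
    if len(aurocs) < 5:
        raise DataError("need at least 5 targets with defined AUROC")
    if len(aurocs) != len(KP_rows):
        raise DataError("aurocs and KP_rows must align")

    def objective(alpha: float, r: float) -> float:
        logA = _log_index_vector(KP_rows, alpha, r)
        if not np.all(np.isfinite(logA)) or np.all(logA == logA[0]):
            return -np.inf
        return float(stats.spearmanr(aurocs, logA).statistic)

    alphas = np.geomspace(alpha_bounds[0], alpha_bounds[1], coarse)
    rs = np.linspace(r_bounds[0], r_bounds[1], coarse)
    best = (-np.inf, alphas[0], rs[0])
    for a in alphas:
        for r in rs:
            v = objective(a, r)
            if v > best[0]:
                best = (v, a, r)
    if not np.isfinite(best[0]):
        raise DataError("degenerate objective: logA constant or undefined everywhere")

    a_span = alphas[1] / alphas[0]  # geometric step
    r_span = rs[1] - rs[0]
    v_best, a_best, r_best = best
    for _ in range(refine_rounds):
        a_lo = max(alpha_bounds[0], a_best / a_span)
        a_hi = min(alpha_bounds[1], a_best * a_span)
        r_lo = max(r_bounds[0], r_best - r_span)
        r_hi = min(r_bounds[1], r_best + r_span)
        for a in np.geomspace(a_lo, a_hi, refine_grid):
            for r in np.linspace(r_lo, r_hi, refine_grid):
                v = objective(a, r)
                if v > v_best:
                    v_best, a_best, r_best = v, a, r
        a_span = a_span ** 0.5
        r_span = r_span / 2.0
    return ApplicabilityParams(alpha=float(a_best), r=float(r_best)), float(v_best)


# ---------------------------------------------------------------------------
# threshold selection and reporting


def select_threshold(
    results: Sequence[tuple[float, float]],
    auroc_cutoff: float = 0.8,
    params: Optional[ApplicabilityParams] = None,
) -> ApplicabilityClassifier:
    """Choose the logA threshold maximizing accuracy of predicting which
    targets exceed the AUROC cutoff.

    ``results`` is a list of (logA, auroc).  Candidate thresholds are the
    midpoints between sorted distinct finite logA values plus one candidate
    below the minimum and one above the maximum; ties in accuracy are broken
    toward the larger threshold (fewer predicted positives).
    """
    logA = np.array([r[0] for r in results], float)
    au = np.array([r[1] for r in results], float)
    truth = au > auroc_cutoff
    if truth.all() or not truth.any():
        raise DataError("threshold selection needs both classes after the AUROC cutoff")
    finite = np.sort(np.unique(logA[np.isfinite(logA)]))
    if len(finite) == 0:
        raise DataError("no finite logA values")
    candidates = [finite[0] - 1.0]
    candidates += [0.5 * (finite[i] + finite[i + 1]) for i in range(len(finite) - 1)]
    candidates += [finite[-1] + 1.0]
    best_thr = candidates[0]
    best_acc = -1.0
    for thr in candidates:
        acc = float(np.mean((logA >= thr) == truth))
        if acc > best_acc or (acc == best_acc and thr > best_thr):
            best_acc, best_thr = acc, thr
    return ApplicabilityClassifier(
        params=params or ApplicabilityParams(alpha=1.0, r=0.5),
        threshold_logA=float(best_thr),
        auroc_cutoff=auroc_cutoff,
        fit_accuracy_=best_acc,
    )


def classification_report(
    predicted: Sequence[bool], truth: Sequence[bool]
) -> ClassificationReport:
    """Confusion counts, PPV, accuracy and two-sided Fisher exact p-value."""
    predicted = np.asarray(predicted, bool)
    truth = np.asarray(truth, bool)
    if len(predicted) != len(truth) or len(predicted) == 0:
        raise DataError("predicted and truth must be equal-length and non-empty")
    tp = int(np.sum(predicted & truth))
    fp = int(np.sum(predicted & ~truth))
    tn = int(np.sum(~predicted & ~truth))
    fn = int(np.sum(~predicted & truth))
    if tp + fp == 0:
        warnings.warn("no predicted positives; PPV undefined")
        ppv, defined = float("nan"), False
    else:
        ppv, defined = tp / (tp + fp), True
    accuracy = (tp + tn) / len(predicted)
    fisher_p = float(stats.fisher_exact([[tp, fp], [fn, tn]], alternative="two-sided")[1])
    return ClassificationReport(tp, fp, tn, fn, ppv, accuracy, fisher_p, defined)
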