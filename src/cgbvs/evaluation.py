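"""Virtual-orphan and half-sampled evaluation protocols with EF1% and AUROC.

A virtual orphan is made by deleting every interaction record of one target
from training while keeping its sequence (so protein features remain
computable).  The full compound table is then screened against that target
and compared to truth labels in which any compound without a positive record
for the target counts as inactive — the treat-missing-as-inactive rule.
Performance is summarized by the enrichment factor at a top fraction
(default 1%) and the area under the ROC curve.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .exceptions import DataError
from .io import NEGATIVE, POSITIVE, UNLABELED, Compound, CPIDataset
from .model import ScreeningResult

ACTIVE = "active"
INACTIVE = "inactive"


@dataclass
class OrphanSplit:
    """Training data with one target's records deleted, plus screening truth."""

    orphan_target_id: str
    train: CPIDataset
    test_truth: dict[str, str]  # compound_id -> {active, inactive}
    gap_flagged: set[str] = field(default_factory=set)


@dataclass
class HalfSampledSplit:
    """Half of one target's records kept for training, the rest as test truth.

    Compounds whose records for the target went into training are excluded
    from the test library.
    """

    target_id: str
    train: CPIDataset
    test_truth: dict[str, str]
    excluded_compounds: set[str]
    seed: int


@dataclass
class EnrichmentResult:
    fraction: float
    N_total: int
    N_subset: int
    A_total: int
    A_found: int
    ef: float


@dataclass
class ROCResult:
    auroc: float
    curve: np.ndarray  # (n_points, 2): columns (FPR, TPR)


# ---------------------------------------------------------------------------
# truth labels and splits


def label_screening_truth(
    dataset: CPIDataset,
    target_id: str,
    library: Sequence[Compound | str],
    gap_policy: str = "inactive",
) -> tuple[dict[str, str], set[str]]:
    """Screening truth for one target over a compound library.

    A compound is active if a positive record exists for (compound, target);
    every other compound — negative, unlabeled (potency gap), or absent from
    the activity table — is inactive.  Gap-potency compounds are returned in
    a flag set so callers can exclude them (``gap_policy='exclude'`` removes
    them from the truth mapping directly).
    """
    if not library:
        raise DataError("empty screening library")
    if gap_policy not in ("inactive", "exclude"):
        raise DataError(f"unknown gap_policy {gap_policy!r}")
    positives = set()
    gap = set()
    for r in dataset.records:
        if r.protein_id != target_id:
            continue
        if r.label == POSITIVE:
            positives.add(r.compound_id)
        elif r.label == UNLABELED:
            gap.add(r.compound_id)
    ids = [c.id if isinstance(c, Compound) else str(c) for c in library]
    truth = {}
    for cid in ids:
        if cid in positives:
            truth[cid] = ACTIVE
        elif cid in gap and gap_policy == "exclude":
            continue
        else:
            truth[cid] = INACTIVE
    return truth, gap & set(ids)


def make_virtual_orphan_split(
    dataset: CPIDataset, target_id: str, gap_policy: str = "inactive"
) -> OrphanSplit:
    """Delete every record of one target from training; truth = full library.

    The orphan's sequence stays in the dataset (sequence knowledge is not
    ligand knowledge); only its interaction records are removed.
    """
    if target_id not in dataset.proteins:
        raise DataError(f"unknown target {target_id!r}")
    n_active = sum(
        1 for r in dataset.records if r.protein_id == target_id and r.label == POSITIVE
    )
    if n_active == 0:
        warnings.warn(
            f"orphan target {target_id!r} has no active records; "
            "screening truth will be all-inactive"
        )
    train = dataset.without_protein_records(target_id)
    truth, gap = label_screening_truth(
        dataset, target_id, list(dataset.compounds), gap_policy=gap_policy
    )
    return OrphanSplit(target_id, train, truth, gap)


def make_half_sampled_split(
    dataset: CPIDataset, target_id: str, seed: int
) -> HalfSampledSplit:
    """Keep a random half of the target's records in training (stratified by
    label), hold out the rest as test truth.

    For odd strata, floor(n/2) records go to train and the remainder to
    test.  Compounds whose target records entered training are omitted from
    the test library, mirroring the half-sampled control protocol.
    """
    if target_id not in dataset.proteins:
        raise DataError(f"unknown target {target_id!r}")
    target_records = [r for r in dataset.records if r.protein_id == target_id]
    if len(target_records) < 2:
        raise DataError(f"target {target_id!r} has fewer than 2 records")
    rng = np.random.default_rng(seed)
    train_recs = [r for r in dataset.records if r.protein_id != target_id]
    held_out = []
    kept = []
    for label in (POSITIVE, NEGATIVE, UNLABELED, None):
        stratum = sorted(
            (r for r in target_records if r.label == label),
            key=lambda r: r.compound_id,
        )
        if not stratum:
            continue
        perm = rng.permutation(len(stratum))
        n_train = len(stratum) // 2
        kept.extend(stratum[i] for i in perm[:n_train])
        held_out.extend(stratum[i] for i in perm[n_train:])
    train = CPIDataset(
        compounds=dict(dataset.compounds),
        proteins=dict(dataset.proteins),
        records=train_recs + kept,
    )
    excluded = {r.compound_id for r in kept}
    truth = {}
    for cid in dataset.compounds:
        if cid in excluded:
            continue
        truth[cid] = INACTIVE
    for r in held_out:
        if r.compound_id in excluded:
            continue
        truth[r.compound_id] = ACTIVE if r.label == POSITIVE else INACTIVE
    return HalfSampledSplit(target_id, train, truth, excluded, seed)


# ---------------------------------------------------------------------------
# metrics


def enrichment_factor(
    ranked: ScreeningResult | Sequence[str],
    truth: Mapping[str, str],
    fraction: float = 0.01,
) -> EnrichmentResult:
    """Enrichment factor at a top fraction of a ranked screen.

    EF = (A_found / N_subset) / (A_total / N_total), where N_subset =
    floor(fraction * N_total) (minimum 1) and A_found is the number of
    actives among the top-N_subset ranked compounds.  1 corresponds to
    random screening; the maximum is min(1/fraction, N_total/A_total).
    """
    ids = ranked.compound_ids if isinstance(ranked, ScreeningResult) else list(ranked)
    if not (0 < fraction <= 1):
        raise DataError("fraction must be in (0, 1]")
    missing = [c for c in ids if c not in truth]
    if missing:
        raise DataError(f"truth labels missing for {len(missing)} ranked compounds")
    N_total = len(ids)
    A_total = sum(1 for c in ids if truth[c] == ACTIVE)
    if A_total == 0:
        raise DataError("enrichment factor undefined: no active compounds in truth")
    N_subset = max(1, math.floor(fraction * N_total))
    A_found = sum(1 for c in ids[:N_subset] if truth[c] == ACTIVE)
    ef = (A_found / N_subset) / (A_total / N_total)
    return EnrichmentResult(fraction, N_total, N_subset, A_total, A_found, ef)


def auroc(
    scores: Sequence[float] | Mapping[str, float],
    truth: Mapping[str, str] | Sequence[str],
) -> ROCResult:
    """AUROC and ROC curve of screening scores against active/inactive truth.

    Equals the Mann-Whitney pair statistic (probability a random active
    outscores a random inactive, with half credit for ties); the curve is a
    threshold sweep starting at (0, 0) and ending at (1, 1).
    """
    if isinstance(scores, Mapping):
        ids = list(scores)
        s = np.array([scores[i] for i in ids], float)
        y = np.array([1 if truth[i] == ACTIVE else 0 for i in ids], int)
    else:
        s = np.asarray(scores, float)
        y = np.array(
            [1 if t in (ACTIVE, 1, True) else 0 for t in truth], int
        )
        if len(s) != len(y):
            raise DataError("scores and truth have different lengths")
    if len(np.unique(y)) < 2:
        raise DataError("AUROC undefined: need both an active and an inactive")
    value = float(roc_auc_score(y, s))
    fpr, tpr, _ = roc_curve(y, s)
    return ROCResult(value, np.column_stack([fpr, tpr]))


def auroc_from_result(result: ScreeningResult, truth: Mapping[str, str]) -> ROCResult:
    scores = {c: float(p) for c, p in zip(result.compound_ids, result.scores)}
    common = {c: scores[c] for c in scores if c in truth}
    return auroc(common, truth)
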