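"""Pairwise-kernel SVM over compound-protein pairs.

One global model is trained on positive/negative interaction pairs using the
product kernel; the SVM decision value (signed distance from the separating
surface) is sigmoid-transformed into an interaction probability, with the
sigmoid fitted on out-of-fold decision values so the calibrator never sees
its own training scores.  Hyperparameters are selected by stratified k-fold
cross-validation maximizing accuracy.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .exceptions import DataError
from .io import POSITIVE, Compound, CPIDataset, Protein
from .kernels import CPIPair, FeatureStore, KernelSpec, kernel_matrix

__all__ = [
    "PairwiseKernelSVC",
    "ScreeningResult",
    "train",
    "decision_score",
    "probability",
    "screen",
]


def _as_pairs(X) -> list[CPIPair]:
    pairs = []
    for item in X:
        if isinstance(item, CPIPair):
            pairs.append(item)
        else:
            cid, pid = item
            pairs.append(CPIPair(str(cid), str(pid)))
    return pairs


def _platt_fit(scores: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Fit sigmoid P(y=1|s) = 1 / (1 + exp(a*s + b)) by penalized ML.

    Uses Platt's target smoothing; returns (a, b) with a < 0 required for a
    probability that increases with the decision score.
    """
    scores = np.asarray(scores, float)
    y = np.asarray(y)
    n_pos = int((y == 1).sum())
    n_neg = len(y) - n_pos
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll_grad(ab):
        a, b = ab
        f = a * scores + b
        loss = float(np.sum(np.logaddexp(0.0, f) - (1.0 - t) * f))
        p = expit(-f)  # P(y=1)
        d = t - p
        return loss, np.array([float(d @ scores), float(d.sum())])

    b0 = np.log((n_neg + 1.0) / (n_pos + 1.0))
    res = minimize(nll_grad, x0=np.array([-1.0, b0]), jac=True, method="BFGS")
    a, b = float(res.x[0]), float(res.x[1])
    if a >= 0:
        raise DataError(
            "sigmoid calibration produced a non-negative slope; decision "
            "scores do not separate the classes"
        )
    return a, b


class PairwiseKernelSVC(ClassifierMixin, BaseEstimator):
    """SVM classifier over compound-protein pairs with a product kernel.

    Parameters
    ----------
    features : FeatureStore
        Resolves compound/protein ids to descriptor vectors.
    kernel_spec : KernelSpec
        Component kernel assignment for the two sides of the product.
    C : float
        SVM regularization strength.
    calibration_folds : int
        Internal folds for fitting the probability sigmoid on out-of-fold
        decision values.
    random_state : int
        Seed for the internal calibration folds.

    Attributes (after fit)
    ----------------------
    support_pairs_ : list[CPIPair]
    dual_coef_ : ndarray, signed dual coefficients (one per support pair)
    intercept_ : float
    calibration_ : (slope, intercept) of the probability sigmoid (slope < 0)
    classes_ : ndarray([0, 1])
    """

    def __init__(
        self,
        features: Optional[FeatureStore] = None,
        kernel_spec: Optional[KernelSpec] = None,
        C: float = 1.0,
        calibration_folds: int = 3,
        random_state: int = 0,
    ):
        self.features = features
        self.kernel_spec = kernel_spec
        self.C = C
        self.calibration_folds = calibration_folds
        self.random_state = random_state

    # -- fitting ----------------------------------------------------------

    def fit(self, X, y, gram: Optional[np.ndarray] = None) -> "PairwiseKernelSVC":
        """Fit on pairs ``X`` (sequence of (compound_id, protein_id)) with
        binary labels ``y`` (1 = interacting); ``gram`` may carry a
        precomputed training Gram matrix."""
        if self.features is None or self.kernel_spec is None:
            raise DataError("features and kernel_spec are required to fit")
        pairs = _as_pairs(X)
        y = np.asarray(y, int)
        classes = np.unique(y)
        if len(classes) != 2 or not set(classes) <= {0, 1}:
            raise DataError("y must contain both classes, coded 0/1")
        if gram is None:
            gram = kernel_matrix(pairs, pairs, self.kernel_spec, self.features)
        svc = SVC(C=self.C, kernel="precomputed")
        svc.fit(gram, y)
        self.classes_ = np.array([0, 1])
        self.train_pairs_ = pairs
        self.support_pairs_ = [pairs[i] for i in svc.support_]
        self.dual_coef_ = svc.dual_coef_[0].copy()
        self.intercept_ = float(svc.intercept_[0])
        self.calibration_ = self._calibrate(gram, y)
        return self

    def _calibrate(self, gram: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        n_min = int(min((y == 0).sum(), (y == 1).sum()))
        n_folds = min(self.calibration_folds, n_min)
        if n_folds < 2:
            warnings.warn(
                "too few examples per class for out-of-fold calibration; "
                "fitting the sigmoid on training decision values"
            )
            svc = SVC(C=self.C, kernel="precomputed")
            svc.fit(gram, y)
            return _platt_fit(svc.decision_function(gram), y)
        oof = np.empty(len(y))
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=self.random_state)
        for tr, te in skf.split(np.zeros(len(y)), y):
            svc = SVC(C=self.C, kernel="precomputed")
            svc.fit(gram[np.ix_(tr, tr)], y[tr])
            oof[te] = svc.decision_function(gram[np.ix_(te, tr)])
        return _platt_fit(oof, y)

    # -- scoring ----------------------------------------------------------

    def decision_function(self, X) -> np.ndarray:
        """Signed distance from the separating surface for each pair."""
        check_is_fitted(self, "dual_coef_")
        pairs = _as_pairs(X)
        K = kernel_matrix(pairs, self.support_pairs_, self.kernel_spec, self.features)
        return K @ self.dual_coef_ + self.intercept_

    def predict_proba(self, X) -> np.ndarray:
        """Calibrated interaction probability, columns ordered [P(0), P(1)]."""
        check_is_fitted(self, "calibration_")
        a, b = self.calibration_
        s = self.decision_function(X)
        p1 = expit(-(a * s + b))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)

    # -- persistence ------------------------------------------------------

    def to_dict(self) -> dict:
        check_is_fitted(self, "dual_coef_")
        ks = self.kernel_spec
        return {
            "kernel_spec": {
                "compound_kernel": ks.compound_kernel,
                "protein_kernel": ks.protein_kernel,
                "compound_gamma": ks.compound_gamma,
                "protein_gamma": ks.protein_gamma,
            },
            "C": self.C,
            "support_pairs": [[p.compound_id, p.protein_id] for p in self.support_pairs_],
            "dual_coef": self.dual_coef_.tolist(),
            "intercept": self.intercept_,
            "calibration": list(self.calibration_),
            "training_fingerprint": getattr(self, "training_fingerprint_", None),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict, features: FeatureStore) -> "PairwiseKernelSVC":
        spec = KernelSpec(**d["kernel_spec"])
        model = cls(features=features, kernel_spec=spec, C=d["C"])
        model.classes_ = np.array([0, 1])
        model.support_pairs_ = [CPIPair(c, p) for c, p in d["support_pairs"]]
        model.dual_coef_ = np.asarray(d["dual_coef"], float)
        model.intercept_ = float(d["intercept"])
        model.calibration_ = tuple(d["calibration"])
        model.training_fingerprint_ = d.get("training_fingerprint")
        return model

    @classmethod
    def load(cls, path: str | Path, features: FeatureStore) -> "PairwiseKernelSVC":
        return cls.from_dict(json.loads(Path(path).read_text()), features)


# ---------------------------------------------------------------------------
# training orchestration


def _dataset_pairs(dataset: CPIDataset) -> tuple[list[CPIPair], np.ndarray]:
    records = sorted(
        dataset.training_records, key=lambda r: (r.compound_id, r.protein_id)
    )
    pairs = [CPIPair(r.compound_id, r.protein_id) for r in records]
    y = np.array([1 if r.label == POSITIVE else 0 for r in records], int)
    return pairs, y


def training_fingerprint(pairs: Sequence[CPIPair], y: np.ndarray, spec: KernelSpec) -> str:
    h = hashlib.sha256()
    for p, lab in zip(pairs, y):
        h.update(f"{p.compound_id}\t{p.protein_id}\t{lab}\n".encode())
    h.update(repr(spec).encode())
    return h.hexdigest()


def train(
    dataset: CPIDataset,
    features: FeatureStore,
    spec: Optional[KernelSpec] = None,
    C_grid: Sequence[float] = (0.1, 1.0, 10.0, 100.0),
    folds: int = 5,
    seed: int = 0,
) -> PairwiseKernelSVC:
    """Train the pairwise-kernel SVM with hyperparameter selection.

    Selects C from ``C_grid`` by maximizing mean accuracy over stratified
    ``folds``-fold cross-validation (ties broken toward smaller C, i.e.
    stronger regularization), then refits on all data and calibrates the
    probability sigmoid.  Records are canonically ordered first so the
    result is invariant to input record order.
    """
    if spec is None:
        spec = KernelSpec.for_descriptors(features.compound, features.protein)
    if not C_grid:
        raise DataError("empty C grid")
    if folds < 2:
        raise DataError("folds must be >= 2")
    pairs, y = _dataset_pairs(dataset)
    if len(np.unique(y)) < 2:
        raise DataError("training needs at least one positive and one negative record")
    gram = kernel_matrix(pairs, pairs, spec, features)
    n_min = int(min((y == 0).sum(), (y == 1).sum()))
    cv_folds = min(folds, n_min)
    cv_results: dict[float, float] = {}
    if cv_folds >= 2 and len(C_grid) > 1:
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        splits = list(skf.split(np.zeros(len(y)), y))
        for C in C_grid:
            accs = []
            for tr, te in splits:
                svc = SVC(C=C, kernel="precomputed")
                svc.fit(gram[np.ix_(tr, tr)], y[tr])
                accs.append(float(np.mean(svc.predict(gram[np.ix_(te, tr)]) == y[te])))
            cv_results[C] = float(np.mean(accs))
        best_acc = max(cv_results.values())
        best_C = min(C for C, a in cv_results.items() if a >= best_acc - 1e-12)
    else:
        best_C = min(C_grid)
    model = PairwiseKernelSVC(
        features=features, kernel_spec=spec, C=best_C, random_state=seed
    )
    model.fit(pairs, y, gram=gram)
    model.cv_results_ = cv_results
    model.best_C_ = best_C
    model.training_fingerprint_ = training_fingerprint(pairs, y, spec)
    return model


def decision_score(model: PairwiseKernelSVC, pair: CPIPair) -> float:
    """Signed distance of one pair from the model's separating surface."""
    return float(model.decision_function([pair])[0])


def probability(model: PairwiseKernelSVC, pair: CPIPair) -> float:
    """Calibrated interaction probability of one pair, in (0, 1)."""
    return float(model.predict_proba([pair])[0, 1])


@dataclass
class ScreeningResult:
    """A ranked screen of a compound library against one target."""

    target_id: str
    compound_ids: list[str]  # descending probability, ties by id ascending
    scores: np.ndarray  # probabilities aligned with compound_ids
    decision_values: np.ndarray


def screen(
    model: PairwiseKernelSVC,
    library: Iterable[Compound | str],
    target: Protein | str,
) -> ScreeningResult:
    """Score every library compound against one target, ranked by probability.

    Ties in probability are broken by compound id ascending so the ranking
    is deterministic and unbiased with respect to activity.
    """
    target_id = target.id if isinstance(target, Protein) else str(target)
    ids = [c.id if isinstance(c, Compound) else str(c) for c in library]
    if not ids:
        raise DataError("empty screening library")
    pairs = [CPIPair(cid, target_id) for cid in ids]
    dec = model.decision_function(pairs)
    a, b = model.calibration_
    prob = expit(-(a * dec + b))
    order = sorted(range(len(ids)), key=lambda i: (-prob[i], ids[i]))
    return ScreeningResult(
        target_id=target_id,
        compound_ids=[ids[i] for i in order],
        scores=prob[order],
        decision_values=dec[order],
    )
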