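"""Compound and protein feature construction.

Compound side: hashed circular (Morgan/ECFP4) fingerprints or imported
precomputed descriptor tables.  Protein side: imported descriptor tables or
the MSA eigen-feature construction — eigendecompose the pairwise
sequence-identity matrix S = UΛUᵀ, drop non-positive eigenpairs, and take
the columns of X = Λ₊^{1/2}U₊ᵀ as per-protein feature vectors, so that the
linear kernel XᵀX is the closest positive-semidefinite approximation of S
(and equals S exactly when S is PSD).  Dense descriptor matrices are
optionally compressed by PCA keeping the smallest number of leading
components reaching a cumulative explained-variance threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import Align, SeqIO
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from .exceptions import DataError
from .io import Compound, LabeledMatrix, Protein

COMPOUND = "compound"
PROTEIN = "protein"


@dataclass
class DescriptorMatrix:
    """Feature vectors for a set of entities (rows = entities)."""

    entity_ids: list[str]
    features: np.ndarray  # (n_entities, n_features)
    kind: str  # "compound" | "protein"
    name: str  # e.g. "ecfp", "msa", "imported"

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise DataError("features must be a 2-D matrix")
        if self.features.shape[0] != len(self.entity_ids):
            raise DataError("row count must match number of entity ids")
        if self.features.shape[1] < 1:
            raise DataError("need at least one feature column")
        if len(set(self.entity_ids)) != len(self.entity_ids):
            raise DataError("entity ids must be unique")
        if not np.all(np.isfinite(self.features)):
            raise DataError("descriptor matrix contains missing/non-finite values")
        self._index = {e: i for i, e in enumerate(self.entity_ids)}

    def vector(self, entity_id: str) -> np.ndarray:
        try:
            return self.features[self._index[entity_id]]
        except KeyError:
            raise DataError(f"no {self.kind} features for id {entity_id!r}") from None

    def rows(self, entity_ids: Sequence[str]) -> np.ndarray:
        return self.features[[self._index[e] for e in entity_ids]]

    def subset(self, entity_ids: Sequence[str]) -> "DescriptorMatrix":
        return DescriptorMatrix(list(entity_ids), self.rows(entity_ids), self.kind, self.name)


@dataclass
class IdentityMatrix:
    """Symmetric pairwise sequence-identity matrix with unit diagonal."""

    protein_ids: list[str]
    S: np.ndarray

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        n = len(self.protein_ids)
        if S.shape != (n, n):
            raise DataError(f"identity matrix shape {S.shape} does not match {n} ids")
        if not np.allclose(S, S.T, atol=1e-8):
            raise DataError("identity matrix is not symmetric (tol 1e-8)")
        if not np.allclose(np.diag(S), 1.0, atol=1e-6):
            raise DataError("identity matrix diagonal must be 1 (tol 1e-6)")
        if S.min() < -1e-8 or S.max() > 1 + 1e-6:
            raise DataError("identity values must lie in [0, 1]")
        np.fill_diagonal(S, 1.0)
        self.S = S


@dataclass
class MSAFeatures:
    """Eigen-features of an identity matrix: per-protein columns of X."""

    protein_ids: list[str]
    X: np.ndarray  # (n_kept, n_proteins); column i is protein i's vector
    eigenvalues_kept: np.ndarray
    eigenvalues_dropped: np.ndarray

    def as_descriptor_matrix(self) -> DescriptorMatrix:
        return DescriptorMatrix(list(self.protein_ids), self.X.T, PROTEIN, "msa")


# ---------------------------------------------------------------------------
# compound fingerprints


def fingerprint(compound: Compound, n_bits: int = 2048, radius: int = 2) -> np.ndarray:
    """Hashed circular fingerprint (ECFP-style, default 2048 bits, radius 2)."""
    mol = Chem.MolFromSmiles(compound.smiles)
    if mol is None:
        raise DataError(f"unparseable SMILES for compound {compound.id!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=float)
    arr[list(fp.GetOnBits())] = 1.0
    return arr


def fingerprint_matrix(
    compounds: Iterable[Compound], n_bits: int = 2048, radius: int = 2
) -> DescriptorMatrix:
    compounds = list(compounds)
    X = np.vstack([fingerprint(c, n_bits=n_bits, radius=radius) for c in compounds])
    return DescriptorMatrix([c.id for c in compounds], X, COMPOUND, "ecfp")


# ---------------------------------------------------------------------------
# imported descriptor tables


def import_descriptors(
    matrix: LabeledMatrix,
    kind: str,
    entity_ids: Optional[Sequence[str]] = None,
    standardize: bool = True,
    name: str = "imported",
) -> DescriptorMatrix:
    """Adopt a precomputed descriptor table for known entities.

    Rows are selected (in dataset order) for ``entity_ids`` when given;
    missing ids are an error listing the offenders.  Columns are
    standardized to mean 0 / sd 1; zero-variance columns are dropped with
    a warning.  Fingerprint-like tables should pass ``standardize=False``.
    """
    if kind not in (COMPOUND, PROTEIN):
        raise DataError(f"kind must be 'compound' or 'protein', got {kind!r}")
    ids = list(matrix.row_labels)
    X = np.asarray(matrix.values, dtype=float)
    if entity_ids is not None:
        index = {e: i for i, e in enumerate(ids)}
        missing = [e for e in entity_ids if e not in index]
        if missing:
            raise DataError(f"descriptor matrix is missing ids: {missing}")
        X = X[[index[e] for e in entity_ids]]
        ids = list(entity_ids)
    if standardize:
        sd = X.std(axis=0, ddof=0)
        keep = sd > 0
        if not keep.all():
            warnings.warn(f"dropping {int((~keep).sum())} zero-variance descriptor column(s)")
        if not keep.any():
            raise DataError("all descriptor columns have zero variance")
        X = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    return DescriptorMatrix(ids, X, kind, name)


# ---------------------------------------------------------------------------
# MSA eigen-features


class MSAEigenTransform(BaseEstimator, TransformerMixin):
    """Protein features from eigendecomposition of a sequence-identity matrix.

    Fitting eigendecomposes S, keeps eigenpairs with eigenvalue above
    ``tol`` (relative to the largest eigenvalue) and forms
    X = Λ₊^{1/2} U₊ᵀ; the per-protein feature vectors are the columns of X.
    The induced linear kernel XᵀX is the Frobenius-closest PSD matrix to S.
    """

    def __init__(self, tol: float = 1e-10):
        self.tol = tol

    def fit(self, S: IdentityMatrix, y=None) -> "MSAEigenTransform":
        lam, U = np.linalg.eigh(S.S)
        cutoff = self.tol * max(lam.max(), 0.0)
        keep = lam > cutoff
        if not keep.any():
            raise DataError("all eigenvalues below tolerance; no features to keep")
        lam_kept = lam[keep]
        # columns of X are the per-protein vectors
        X = (np.sqrt(lam_kept)[:, None]) * U[:, keep].T
        self.protein_ids_ = list(S.protein_ids)
        self.X_ = X
        self.eigenvalues_kept_ = lam_kept
        self.eigenvalues_dropped_ = lam[~keep][lam[~keep] < 0]
        return self

    def transform(self, S: IdentityMatrix) -> np.ndarray:
        check_is_fitted(self, "X_")
        index = {p: i for i, p in enumerate(self.protein_ids_)}
        cols = [index[p] for p in S.protein_ids]
        return self.X_[:, cols].T

    def features_(self) -> MSAFeatures:
        check_is_fitted(self, "X_")
        return MSAFeatures(
            protein_ids=list(self.protein_ids_),
            X=self.X_,
            eigenvalues_kept=self.eigenvalues_kept_,
            eigenvalues_dropped=self.eigenvalues_dropped_,
        )


def msa_features(S: IdentityMatrix, tol: float = 1e-10) -> MSAFeatures:
    """Eigen-feature vectors of an identity matrix (see MSAEigenTransform)."""
    return MSAEigenTransform(tol=tol).fit(S).features_()


# ---------------------------------------------------------------------------
# PCA reduction


class PCAReducer(BaseEstimator, TransformerMixin):
    """PCA keeping the fewest leading components reaching a cumulative
    explained-variance threshold (default 99%).

    Projection parameters are retained so held-out entities can be projected
    into the fitted space.
    """

    def __init__(self, cumulative: float = 0.99):
        self.cumulative = cumulative

    def fit(self, X, y=None) -> "PCAReducer":
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise DataError("PCA requires at least 2 entities")
        full = PCA(svd_solver="full")
        full.fit(X)
        csum = np.cumsum(full.explained_variance_ratio_)
        k = int(np.searchsorted(csum, self.cumulative - 1e-12) + 1)
        k = min(k, len(csum))
        self.n_components_ = k
        self.components_ = full.components_[:k]
        self.mean_ = full.mean_
        self.explained_variance_ratio_ = full.explained_variance_ratio_[:k]
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "components_")
        return (np.asarray(X, dtype=float) - self.mean_) @ self.components_.T


def pca_reduce(
    D: DescriptorMatrix, cumulative: float = 0.99
) -> tuple[DescriptorMatrix, PCAReducer]:
    """Reduce a descriptor matrix to its leading principal components."""
    reducer = PCAReducer(cumulative=cumulative).fit(D.features)
    scores = reducer.transform(D.features)
    return DescriptorMatrix(list(D.entity_ids), scores, D.kind, D.name + "_pca"), reducer


# ---------------------------------------------------------------------------
# pairwise sequence identity


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -0.5
    return aligner


def _identity_from_aligned(a: str, b: str) -> float:
    """Fraction of identical columns over columns with >=1 residue."""
    num = den = 0
    for x, y in zip(a, b):
        gx, gy = x == "-", y == "-"
        if gx and gy:
            continue
        den += 1
        if not gx and not gy and x == y:
            num += 1
    if den == 0:
        return 0.0
    return num / den


def pairwise_identity(
    proteins: Sequence[Protein],
    alignment: Optional[str | Path | dict[str, str]] = None,
) -> IdentityMatrix:
    """Pairwise percent-identity matrix for a set of proteins.

    With ``alignment`` (aligned FASTA path or id -> aligned-sequence map),
    identities are read off the given multiple alignment.  Otherwise each
    pair is globally aligned by the built-in fallback aligner.  Identity is
    the fraction of alignment columns with identical residues over columns
    where at least one of the two sequences has a residue (both-gap columns
    are excluded).
    """
    proteins = list(proteins)
    if not proteins:
        raise DataError("empty sequence set")
    ids = [p.id for p in proteins]
    n = len(proteins)
    S = np.eye(n)

    if alignment is not None:
        if isinstance(alignment, (str, Path)):
            aligned = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(alignment), "fasta")}
        else:
            aligned = {k: v.upper() for k, v in alignment.items()}
        missing = [i for i in ids if i not in aligned]
        if missing:
            raise DataError(f"alignment is missing sequences for: {missing}")
        lengths = {len(aligned[i]) for i in ids}
        if len(lengths) != 1:
            raise DataError("aligned sequences must all have the same length")
        for i in range(n):
            for j in range(i + 1, n):
                S[i, j] = S[j, i] = _identity_from_aligned(aligned[ids[i]], aligned[ids[j]])
        return IdentityMatrix(ids, S)

    aligner = _make_aligner()
    for i in range(n):
        for j in range(i + 1, n):
            aln = aligner.align(proteins[i].sequence, proteins[j].sequence)[0]
            a, b = str(aln[0]), str(aln[1])
            S[i, j] = S[j, i] = _identity_from_aligned(a, b)
    return IdentityMatrix(ids, S)


def identity_from_labeled_matrix(matrix: LabeledMatrix) -> IdentityMatrix:
    """Adopt a precomputed identity matrix (e.g. aligner percent-identity).

    Values are rescaled from percent to [0, 1] when any entry exceeds 1 and
    the diagonal is forced to 1 (within tolerance 1e-6 after rescaling).
    """
    S = np.asarray(matrix.values, dtype=float)
    if matrix.row_labels != matrix.col_labels:
        raise DataError("identity matrix must have matching row/column labels")
    if S.max() > 1.0 + 1e-9:
        S = S / 100.0
    if not np.allclose(np.diag(S), 1.0, atol=1e-6):
        raise DataError("identity matrix diagonal must be 1 (or 100%)")
    return IdentityMatrix(list(matrix.row_labels), S)
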