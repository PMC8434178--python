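"""Self-contained synthetic multi-target interaction benchmarks.

The generators emulate the structure of a multi-target ligand corpus:
families of related protein targets (sequences mutated from shared
ancestors, so the realized pairwise-identity matrix matches a block design)
whose active ligands share family-specific fingerprint bit motifs, with
ligand sharing between related targets scaled by sequence identity.  The
compound side is deliberately abstract — planted bit motifs rather than
realistic chemistry — which makes the strength of the transferable signal a
controllable dial and keeps end-to-end tests fast.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .descriptors import COMPOUND, DescriptorMatrix, IdentityMatrix
from .exceptions import DataError
from .io import (
    NEGATIVE,
    POSITIVE,
    ActivityRecord,
    Compound,
    CPIDataset,
    LabeledMatrix,
    Protein,
    write_activities,
    write_matrix,
    write_proteins,
)

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class FixtureSpec:
    """Design of a synthetic multi-target benchmark.

    ``family_sizes`` partitions the targets into families; members of one
    family share ``intra_identity`` pairwise sequence identity and
    ``inter_identity`` across families.  ``sharing_rate`` controls both how
    much of a family's bit motif each member reuses and the probability
    that a ligand of one member is also recorded active on a related member
    (scaled by identity).
    """

    n_targets: int = 6
    n_compounds: int = 2000
    family_sizes: tuple[int, ...] = (3, 3)
    intra_identity: float = 0.8
    inter_identity: float = 0.3
    actives_per_target: int = 100
    inactives_per_target: int = 100
    sharing_rate: float = 0.8
    noise_rate: float = 0.0
    n_bits: int = 256
    motif_bits: int = 16
    bg_density: float = 0.05
    seq_length: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_targets, self.n_compounds, self.actives_per_target) < 1:
            raise DataError("all counts must be positive")
        if sum(self.family_sizes) != self.n_targets:
            raise DataError("family_sizes must sum to n_targets")
        for rate in (self.sharing_rate, self.noise_rate, self.bg_density):
            if not 0 <= rate <= 1:
                raise DataError("rates must lie in [0, 1]")
        if not 0 <= self.inter_identity <= self.intra_identity <= 1:
            raise DataError("need 0 <= inter_identity <= intra_identity <= 1")
        need = self.n_targets * (self.actives_per_target + self.inactives_per_target)
        if need > self.n_compounds:
            raise DataError(
                f"requested {need} labeled compounds but only "
                f"{self.n_compounds} available"
            )

    @property
    def family_of(self) -> list[int]:
        fam = []
        for f, size in enumerate(self.family_sizes):
            fam.extend([f] * size)
        return fam


@dataclass
class FixtureData:
    """A generated benchmark: dataset + planted fingerprints + identity."""

    spec: FixtureSpec
    dataset: CPIDataset
    compound_features: DescriptorMatrix  # planted binary fingerprints
    identity: IdentityMatrix
    target_motifs: dict[str, np.ndarray]  # target id -> motif bit indices


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    hits = rng.random(len(seq)) < rate
    for i in np.flatnonzero(hits):
        choices = _AA[_AA != out[i]]
        out[i] = rng.choice(choices)
    return out


def generate_protein_family(
    spec: FixtureSpec,
) -> tuple[list[Protein], IdentityMatrix]:
    """Sequences mutated from family ancestors so realized pairwise identity
    matches the block design (within sampling noise, about +-0.05).

    With intra-family identity q_in and inter-family q_out, members mutate
    from their family ancestor at rate 1 - sqrt(q_in) and family ancestors
    from a common root at rate 1 - sqrt(q_out / q_in), so that expected
    identities multiply out to the design values (plus a small bonus from
    coincidental matches).
    """
    rng = np.random.default_rng(spec.seed)
    root = rng.choice(_AA, size=spec.seq_length)
    member_rate = 1.0 - math.sqrt(spec.intra_identity)
    if spec.intra_identity > 0:
        ancestor_rate = 1.0 - math.sqrt(spec.inter_identity / spec.intra_identity)
    else:
        ancestor_rate = 1.0
    proteins: list[Protein] = []
    idx = 0
    seqs: list[np.ndarray] = []
    for size in spec.family_sizes:
        ancestor = _mutate(root, ancestor_rate, rng)
        for _ in range(size):
            member = _mutate(ancestor, member_rate, rng)
            proteins.append(Protein(f"T{idx}", "".join(member)))
            seqs.append(member)
            idx += 1
    n = len(proteins)
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = float(np.mean(seqs[i] == seqs[j]))
    return proteins, IdentityMatrix([p.id for p in proteins], S)


def generate_cpi_dataset(spec: FixtureSpec) -> FixtureData:
    """Planted-rule interaction dataset.

    Each target's actives are background bit vectors with that target's
    motif bits all set, so a nearest-motif rule is perfect at noise 0;
    members of one family reuse each family-motif bit with probability
    ``sharing_rate`` (private bits otherwise), and actives of one member
    are cross-recorded on related members with probability
    ``sharing_rate * identity``.  Labels are flipped at ``noise_rate``.
    """
    rng = np.random.default_rng(spec.seed + 1)
    proteins, identity = generate_protein_family(spec)
    family_of = spec.family_of
    n_fam = len(spec.family_sizes)

    # disjoint bit pools: one per family plus one per target for private bits
    pool_size = spec.motif_bits
    needed = pool_size * (n_fam + spec.n_targets)
    if needed > spec.n_bits:
        raise DataError(
            f"n_bits={spec.n_bits} too small for {needed} reserved motif bits"
        )
    cursor = 0
    family_pool = []
    for _ in range(n_fam):
        family_pool.append(np.arange(cursor, cursor + pool_size))
        cursor += pool_size
    private_pool = []
    for _ in range(spec.n_targets):
        private_pool.append(np.arange(cursor, cursor + pool_size))
        cursor += pool_size

    target_motifs: dict[str, np.ndarray] = {}
    for t, prot in enumerate(proteins):
        shared = rng.random(pool_size) < spec.sharing_rate
        motif = np.where(shared, family_pool[family_of[t]], private_pool[t])
        target_motifs[prot.id] = motif

    compounds: list[Compound] = []
    fingerprints: list[np.ndarray] = []
    records: list[ActivityRecord] = []

    def new_compound(bits: np.ndarray) -> str:
        cid = f"C{len(compounds):05d}"
        compounds.append(Compound(cid, "C"))
        fingerprints.append(bits)
        return cid

    S = identity.S
    for t, prot in enumerate(proteins):
        for _ in range(spec.actives_per_target):
            bits = (rng.random(spec.n_bits) < spec.bg_density).astype(float)
            bits[target_motifs[prot.id]] = 1.0
            cid = new_compound(bits)
            records.append(
                ActivityRecord(cid, prot.id, potency=float(rng.uniform(0.01, 1.0)),
                               label=POSITIVE)
            )
            for t2, prot2 in enumerate(proteins):
                if t2 == t or family_of[t2] != family_of[t]:
                    continue
                if rng.random() < spec.sharing_rate * S[t, t2]:
                    # a shared ligand carries both targets' motifs
                    bits[target_motifs[prot2.id]] = 1.0
                    records.append(
                        ActivityRecord(cid, prot2.id,
                                       potency=float(rng.uniform(0.01, 1.0)),
                                       label=POSITIVE)
                    )
        for _ in range(spec.inactives_per_target):
            bits = (rng.random(spec.n_bits) < spec.bg_density).astype(float)
            cid = new_compound(bits)
            records.append(
                ActivityRecord(cid, prot.id, potency=float(rng.uniform(5.0, 100.0)),
                               label=NEGATIVE)
            )
    while len(compounds) < spec.n_compounds:
        new_compound((rng.random(spec.n_bits) < spec.bg_density).astype(float))

    if spec.noise_rate > 0:
        for rec in records:
            if rng.random() < spec.noise_rate:
                rec.label = NEGATIVE if rec.label == POSITIVE else POSITIVE

    # duplicate (compound, protein) pairs can arise from cross-recording;
    # keep the first occurrence
    seen: set[tuple[str, str]] = set()
    unique_records = []
    for rec in records:
        key = (rec.compound_id, rec.protein_id)
        if key in seen:
            continue
        seen.add(key)
        unique_records.append(rec)

    dataset = CPIDataset(
        compounds={c.id: c for c in compounds},
        proteins={p.id: p for p in proteins},
        records=unique_records,
    ).validate()
    features = DescriptorMatrix(
        [c.id for c in compounds], np.vstack(fingerprints), COMPOUND, "ecfp"
    )
    return FixtureData(spec, dataset, features, identity, target_motifs)


# ---------------------------------------------------------------------------
# applicability benchmark


@dataclass
class ApplicabilityBenchmark:
    target_ids: list[str]
    KP: np.ndarray  # symmetric protein-kernel matrix, unit diagonal
    active_counts: np.ndarray
    aurocs: np.ndarray
    neighbors: list[list[tuple[str, float, float]]]
    planted_alpha: float
    planted_r: float


def generate_applicability_benchmark(
    n_targets: int = 50,
    planted_alpha: float = 10.0,
    planted_r: float = 0.5,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> ApplicabilityBenchmark:
    """Benchmark with AUROC a noisy monotone function of the planted index.

    Protein-kernel values are drawn uniformly in [0, 1], active-ligand
    counts log-uniformly in [10, ~3000]; the simulated AUROC is
    0.5 + 0.5 * sigmoid(2 z) + noise (z = standardized logA at the planted
    parameters), clipped to [0.5, 1].  At noise_sd = 0 the Spearman
    correlation with logA at the planted parameters is exactly 1.
    """
    if not (0.1 <= planted_alpha <= 200 and 0 <= planted_r <= 1):
        raise DataError("planted parameters must lie within the fitting bounds")
    rng = np.random.default_rng(seed)
    ids = [f"T{i}" for i in range(n_targets)]
    KP = rng.uniform(0, 1, size=(n_targets, n_targets))
    KP = (KP + KP.T) / 2
    np.fill_diagonal(KP, 1.0)
    counts = np.round(10 ** rng.uniform(1.0, 3.5, size=n_targets)).astype(float)
    from scipy.special import expit

    neighbors = []
    logA = np.empty(n_targets)
    for i in range(n_targets):
        row = [(ids[j], float(KP[i, j]), float(counts[j]))
               for j in range(n_targets) if j != i]
        neighbors.append(row)
        kp = np.array([v[1] for v in row])
        nj = np.array([v[2] for v in row])
        logA[i] = math.log(float(expit(planted_alpha * (kp - planted_r)) @ nj))
    z = (logA - logA.mean()) / logA.std()
    aurocs = 0.5 + 0.5 * expit(2.0 * z)
    if noise_sd > 0:
        aurocs = np.clip(aurocs + rng.normal(0, noise_sd, n_targets), 0.5, 1.0)
    return ApplicabilityBenchmark(
        ids, KP, counts, aurocs, neighbors, planted_alpha, planted_r
    )


# ---------------------------------------------------------------------------
# writing fixtures in the formats the loaders read


def write_fixture(directory: str | Path, data: FixtureData) -> dict[str, Path]:
    """Write a fixture in the exact on-disk formats the I/O layer reads."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "compounds": directory / "compounds.csv",
        "fingerprints": directory / "fingerprints.csv",
        "proteins": directory / "proteins.fasta",
        "activities": directory / "activities.csv",
        "identity": directory / "identity.csv",
    }
    with open(paths["compounds"], "w") as fh:
        fh.write("id,smiles\n")
        for c in data.dataset.compounds.values():
            fh.write(f"{c.id},{c.smiles}\n")
    fp = data.compound_features
    write_matrix(
        paths["fingerprints"],
        LabeledMatrix(list(fp.entity_ids),
                      [f"b{i}" for i in range(fp.features.shape[1])],
                      fp.features),
    )
    write_proteins(paths["proteins"], data.dataset.proteins.values())
    write_activities(paths["activities"], data.dataset.records)
    write_matrix(
        paths["identity"],
        LabeledMatrix(list(data.identity.protein_ids),
                      list(data.identity.protein_ids),
                      data.identity.S),
    )
    return paths
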