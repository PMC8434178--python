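"""Domain types and file I/O for compounds, proteins, activity tables and matrices.

Compound structures arrive as SMILES (plain ``SMILES<tab>id`` lines or a CSV
with ``id,smiles`` columns), protein sequences as FASTA, and bioactivity as a
CSV of (compound_id, protein_id, potency_um, label) rows.  Labeled matrices
(descriptors, sequence-identity) are CSV with a header row and first-column
labels; the whitespace-separated distance-matrix dialect emitted by common
aligners is also accepted.
"""

from __future__ import annotations

import csv
import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from rdkit import Chem
from rdkit import RDLogger

from .exceptions import DataError

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.error")

POSITIVE = "positive"
NEGATIVE = "negative"
UNLABELED = "unlabeled"
_LABELS = (POSITIVE, NEGATIVE, UNLABELED)

#: the 20 standard amino acids plus the common ambiguity/rare letters
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY" + "XBZU")


@dataclass(frozen=True)
class Compound:
    """A small molecule identified by ``id`` with its SMILES as given."""

    id: str
    smiles: str


@dataclass(frozen=True)
class Protein:
    """A protein target identified by ``id`` with its amino-acid sequence."""

    id: str
    sequence: str


@dataclass
class ActivityRecord:
    """One measured or asserted compound-protein interaction.

    ``potency`` is in micromolar; ``label`` is one of ``positive``,
    ``negative`` or ``unlabeled`` (or ``None`` before labeling).
    """

    compound_id: str
    protein_id: str
    potency: Optional[float] = None
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.potency is None and self.label is None:
            raise DataError(
                f"record ({self.compound_id}, {self.protein_id}): "
                "at least one of potency/label must be present"
            )
        if self.label is not None and self.label not in _LABELS:
            raise DataError(f"unknown label {self.label!r}")


@dataclass
class CPIDataset:
    """Compounds, proteins, and labeled interaction records.

    ``compounds`` and ``proteins`` are insertion-ordered id -> entity maps;
    every record must reference entities present in them.
    """

    compounds: dict[str, Compound] = field(default_factory=dict)
    proteins: dict[str, Protein] = field(default_factory=dict)
    records: list[ActivityRecord] = field(default_factory=list)

    def validate(self) -> "CPIDataset":
        for r in self.records:
            if r.compound_id not in self.compounds:
                raise DataError(f"record references unknown compound {r.compound_id!r}")
            if r.protein_id not in self.proteins:
                raise DataError(f"record references unknown protein {r.protein_id!r}")
        return self

    @property
    def training_records(self) -> list[ActivityRecord]:
        """Records usable for training: explicitly positive or negative."""
        return [r for r in self.records if r.label in (POSITIVE, NEGATIVE)]

    def records_for_protein(self, protein_id: str) -> list[ActivityRecord]:
        return [r for r in self.records if r.protein_id == protein_id]

    def without_protein_records(self, protein_id: str) -> "CPIDataset":
        """A copy with every record touching ``protein_id`` removed.

        Compounds and proteins (including ``protein_id`` itself) are kept:
        sequence knowledge is not ligand knowledge.
        """
        return CPIDataset(
            compounds=dict(self.compounds),
            proteins=dict(self.proteins),
            records=[r for r in self.records if r.protein_id != protein_id],
        )


@dataclass
class LabeledMatrix:
    """A numeric matrix with row and column labels, as read from CSV."""

    row_labels: list[str]
    col_labels: list[str]
    values: np.ndarray


# ---------------------------------------------------------------------------
# loaders


def _parse_smiles(smiles: str) -> bool:
    return Chem.MolFromSmiles(smiles) is not None


def load_compounds(path: str | Path) -> list[Compound]:
    """Load compounds from a SMILES file or a CSV with id/smiles columns.

    Unparseable structures are skipped with a warning carrying the line
    number; zero valid compounds is a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"compound file not found: {path}")
    text = path.read_text()
    rows: list[tuple[int, str, str]] = []  # (lineno, id, smiles)
    lines = text.splitlines()
    is_csv = bool(lines) and ("," in lines[0])
    if is_csv:
        reader = csv.DictReader(lines)
        if reader.fieldnames is None or not {"id", "smiles"} <= set(
            h.strip().lower() for h in reader.fieldnames
        ):
            raise DataError(f"{path}: CSV must have 'id' and 'smiles' columns")
        keymap = {h.strip().lower(): h for h in reader.fieldnames}
        for lineno, row in enumerate(reader, start=2):
            rows.append((lineno, row[keymap["id"]].strip(), row[keymap["smiles"]].strip()))
    else:
        # SMILES file: "SMILES<whitespace>id" per line
        for lineno, line in enumerate(lines, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                warnings.warn(f"{path}:{lineno}: missing id, line skipped")
                continue
            rows.append((lineno, parts[1], parts[0]))

    compounds: dict[str, Compound] = {}
    n_bad = 0
    for lineno, cid, smiles in rows:
        if not _parse_smiles(smiles):
            warnings.warn(f"{path}:{lineno}: unparseable SMILES {smiles!r}, skipped")
            n_bad += 1
            continue
        if cid in compounds:
            raise DataError(f"{path}:{lineno}: duplicate compound id {cid!r}")
        compounds[cid] = Compound(cid, smiles)
    if n_bad:
        logger.info("skipped %d unparseable compound rows from %s", n_bad, path)
    if not compounds:
        raise DataError(f"{path}: no valid compounds")
    return list(compounds.values())


def load_proteins(path: str | Path) -> list[Protein]:
    """Load proteins from FASTA; the header token before whitespace is the id.

    Sequences are uppercased; records with letters outside the 20 standard
    amino acids (plus X/B/Z/U) are rejected with a warning.  Duplicate ids
    are a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"FASTA file not found: {path}")
    proteins: dict[str, Protein] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if rec.id in proteins:
            raise DataError(f"{path}: duplicate protein id {rec.id!r}")
        if not seq:
            warnings.warn(f"{path}: empty sequence for {rec.id!r}, rejected")
            continue
        bad = set(seq) - PROTEIN_ALPHABET
        if bad:
            warnings.warn(
                f"{path}: {rec.id!r} contains illegal residue letters "
                f"{sorted(bad)}, rejected"
            )
            continue
        proteins[rec.id] = Protein(rec.id, seq)
    return list(proteins.values())


def write_proteins(path: str | Path, proteins: Iterable[Protein]) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.id}\n{p.sequence}\n")


def load_activities(path: str | Path) -> list[ActivityRecord]:
    """Read an activity CSV (compound_id, protein_id, potency_um?, label?)."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"activity file not found: {path}")
    df = pd.read_csv(path, dtype={"compound_id": str, "protein_id": str})
    required = {"compound_id", "protein_id"}
    if not required <= set(df.columns):
        raise DataError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    records = []
    for _, row in df.iterrows():
        potency = row.get("potency_um")
        if potency is not None and (potency != potency):  # NaN
            potency = None
        label = row.get("label")
        if label is not None and (not isinstance(label, str) or not label):
            label = None
        records.append(
            ActivityRecord(
                compound_id=row["compound_id"],
                protein_id=row["protein_id"],
                potency=float(potency) if potency is not None else None,
                label=label,
            )
        )
    return records


def write_activities(path: str | Path, records: Iterable[ActivityRecord]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["compound_id", "protein_id", "potency_um", "label"])
        for r in records:
            w.writerow([r.compound_id, r.protein_id,
                        "" if r.potency is None else repr(r.potency),
                        r.label or ""])


def label_activities(
    records: Sequence[ActivityRecord],
    active_max: float = 1.0,
    inactive_min: float = 3.0,
) -> list[ActivityRecord]:
    """Assign binary activity labels from potency thresholds.

    Potency <= ``active_max`` uM is positive, >= ``inactive_min`` uM negative,
    and the open gap in between is marked unlabeled (excluded downstream).
    Records with a pre-existing explicit label pass through untouched;
    records with a non-positive potency are rejected with a warning.
    """
    if not active_max < inactive_min:
        raise DataError("active_max must be strictly below inactive_min")
    out: list[ActivityRecord] = []
    for r in records:
        if r.label is not None:
            out.append(r)
            continue
        if r.potency is None or not math.isfinite(r.potency) or r.potency <= 0:
            warnings.warn(
                f"record ({r.compound_id}, {r.protein_id}): "
                f"non-positive or missing potency {r.potency!r}, rejected"
            )
            continue
        if r.potency <= active_max:
            label = POSITIVE
        elif r.potency >= inactive_min:
            label = NEGATIVE
        else:
            label = UNLABELED
        out.append(replace(r, label=label))
    return out


def build_dataset(
    compounds: Iterable[Compound],
    proteins: Iterable[Protein],
    records: Iterable[ActivityRecord],
) -> CPIDataset:
    """Assemble a validated dataset with the duplicate-pair policy applied.

    For duplicated (compound, protein) pairs the most potent measurement
    (minimum uM) is kept; pairs with conflicting explicit labels and no
    potency to arbitrate are dropped with a warning.
    """
    cmap = {c.id: c for c in compounds}
    pmap = {p.id: p for p in proteins}
    grouped: dict[tuple[str, str], list[ActivityRecord]] = {}
    for r in records:
        grouped.setdefault((r.compound_id, r.protein_id), []).append(r)
    deduped: list[ActivityRecord] = []
    for key, group in grouped.items():
        if len(group) == 1:
            deduped.append(group[0])
            continue
        with_potency = [r for r in group if r.potency is not None]
        if with_potency:
            deduped.append(min(with_potency, key=lambda r: r.potency))
        else:
            labels = {r.label for r in group}
            if len(labels) > 1:
                warnings.warn(f"pair {key}: conflicting explicit labels, dropped")
            else:
                deduped.append(group[0])
    return CPIDataset(compounds=cmap, proteins=pmap, records=deduped).validate()


# ---------------------------------------------------------------------------
# labeled matrices


def read_matrix(path: str | Path) -> LabeledMatrix:
    """Read a labeled numeric matrix.

    Accepts a CSV with a header row and first-column row labels, or the
    aligner distance-matrix dialect (optional leading count line, then one
    ``label value value ...`` row per entity; column labels are then the row
    labels).  Ragged rows, blank/non-numeric cells and duplicate labels are
    errors naming the offending cell.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"matrix file not found: {path}")
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise DataError(f"{path}: empty matrix file")
    if "," in lines[0]:
        return _read_matrix_csv(path, lines)
    return _read_matrix_whitespace(path, lines)


def _read_matrix_csv(path: Path, lines: list[str]) -> LabeledMatrix:
    reader = list(csv.reader(lines))
    header = reader[0]
    col_labels = [h.strip() for h in header[1:]]
    row_labels: list[str] = []
    rows: list[list[float]] = []
    for i, row in enumerate(reader[1:], start=2):
        if len(row) != len(header):
            raise DataError(f"{path}: row {i} has {len(row)} cells, expected {len(header)}")
        row_labels.append(row[0].strip())
        vals = []
        for j, cell in enumerate(row[1:], start=1):
            cell = cell.strip()
            if not cell:
                raise DataError(f"{path}: blank cell at row {i}, column {header[j]!r}")
            try:
                vals.append(float(cell))
            except ValueError:
                raise DataError(
                    f"{path}: non-numeric cell {cell!r} at row {i}, column {header[j]!r}"
                ) from None
        rows.append(vals)
    _check_unique(path, row_labels, "row")
    _check_unique(path, col_labels, "column")
    return LabeledMatrix(row_labels, col_labels, np.asarray(rows, dtype=float))


def _read_matrix_whitespace(path: Path, lines: list[str]) -> LabeledMatrix:
    # aligner dialect: optional leading integer count, then "label v v v ..."
    start = 0
    first = lines[0].split()
    if len(first) == 1:
        try:
            int(first[0])
            start = 1
        except ValueError:
            pass
    row_labels: list[str] = []
    rows: list[list[float]] = []
    for i, line in enumerate(lines[start:], start=start + 1):
        parts = line.split()
        row_labels.append(parts[0])
        try:
            rows.append([float(v) for v in parts[1:]])
        except ValueError as exc:
            raise DataError(f"{path}: non-numeric cell in row {i}: {exc}") from None
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise DataError(f"{path}: ragged rows (widths {sorted(widths)})")
    _check_unique(path, row_labels, "row")
    return LabeledMatrix(row_labels, list(row_labels), np.asarray(rows, dtype=float))


def _check_unique(path: Path, labels: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise DataError(f"{path}: duplicate {kind} label {lab!r}")
        seen.add(lab)


def write_matrix(path: str | Path, matrix: LabeledMatrix) -> None:
    """Write a labeled matrix as CSV at full float precision (round-trip safe)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([""] + list(matrix.col_labels))
        for lab, row in zip(matrix.row_labels, matrix.values):
            w.writerow([lab] + [repr(float(v)) for v in row])
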