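"""Reading, writing and validation of peptide datasets and 20x6 matrices.

The package works with labeled hexapeptides (six-residue peptides over the
20 standard one-letter amino acid codes) and with position-specific
20 x 6 value tables (propensities or statistical potentials). Datasets are
stored either as two-column TSV files (``sequence<TAB>label``) or FASTA
files whose description lines carry a ``|label`` suffix. Matrices are TSV
files with a ``res`` column and position columns ``1..6``.

Bundled reference data (the two published potential matrices, the globular
background composition and the shipped property-scale file) is exposed via
the ``load_*`` helpers at the bottom of this module.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

#: Canonical residue ordering used by every matrix in the package
#: (alphabetical one-letter codes).
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Number of residues and of positions in a hexapeptide.
N_RESIDUES: int = 20
N_POSITIONS: int = 6

#: Residue one-letter code -> row index in matrix arrays.
RESIDUE_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


class PeptideIOError(ValueError):
    """Raised for malformed dataset or matrix files."""


class ValidationError(ValueError):
    """Raised when a sequence or record violates the alphabet/length rules."""


class Label(str, enum.Enum):
    """Experimental class of a hexapeptide."""

    AMYLOID = "amyloid"
    NON_AMYLOID = "non_amyloid"
    UNLABELED = "unlabeled"

    @classmethod
    def parse(cls, token: str) -> "Label":
        norm = token.strip().lower().replace("-", "_")
        try:
            return cls(norm)
        except ValueError:
            raise PeptideIOError(
                f"unknown label {token!r}; expected 'amyloid', 'non_amyloid' "
                "or 'unlabeled'"
            ) from None


def validate_sequence(sequence: str, *, hexa: bool = True) -> str:
    """Validate residue alphabet (and, by default, hexapeptide length).

    Strictly the 20 standard one-letter codes are accepted; ambiguity codes
    (B/Z/X), selenocysteine (U) and lowercase letters are rejected rather
    than mapped, because every table in the method enumerates exactly 20
    residues.
    """
    if not isinstance(sequence, str) or not sequence:
        raise ValidationError("sequence must be a non-empty string")
    bad = sorted({c for c in sequence if c not in RESIDUE_INDEX})
    if bad:
        raise ValidationError(
            f"sequence {sequence!r} contains invalid residue code(s) {bad}; "
            f"allowed: {AMINO_ACIDS}"
        )
    if hexa and len(sequence) != N_POSITIONS:
        raise ValidationError(
            f"sequence {sequence!r} has length {len(sequence)}, expected "
            f"{N_POSITIONS}"
        )
    return sequence


def encode_sequence(sequence: str) -> np.ndarray:
    """Map a residue string to an integer index array (no validation)."""
    return np.fromiter(
        (RESIDUE_INDEX[c] for c in sequence), dtype=np.intp, count=len(sequence)
    )


@dataclass(frozen=True)
class PeptideRecord:
    """A single (possibly labeled) hexapeptide."""

    id: str
    sequence: str
    label: Label = Label.UNLABELED


@dataclass
class PeptideDataset:
    """Ordered collection of labeled hexapeptide records.

    Duplicate ``(sequence, label)`` pairs are rejected on construction
    unless ``allow_duplicates`` is set, mirroring the redundancy
    elimination applied to the experimental compilations. The same
    sequence carrying *conflicting* labels is always an error.
    """

    records: list[PeptideRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._check(self.records, allow_duplicates=False, allow_conflicts=False)

    @classmethod
    def from_records(
        cls,
        records: Iterable[PeptideRecord],
        *,
        allow_duplicates: bool = False,
        allow_conflicts: bool = False,
    ) -> "PeptideDataset":
        """Build a dataset with configurable redundancy policy.

        ``allow_duplicates`` permits repeated (sequence, label) pairs;
        ``allow_conflicts`` permits one sequence in both classes. Files
        are always loaded with conflicts forbidden; the synthetic sampler
        allows both, since overlapping classes are part of its model.
        """
        records = list(records)
        cls._check(records, allow_duplicates=allow_duplicates,
                   allow_conflicts=allow_conflicts)
        ds = cls.__new__(cls)
        ds.records = records
        return ds

    @staticmethod
    def _check(records: Sequence[PeptideRecord], *, allow_duplicates: bool,
               allow_conflicts: bool) -> None:
        seen: dict[tuple[str, Label], str] = {}
        by_seq: dict[str, Label] = {}
        for rec in records:
            validate_sequence(rec.sequence)
            key = (rec.sequence, rec.label)
            if key in seen and not allow_duplicates:
                raise PeptideIOError(
                    f"duplicate record {rec.sequence!r} with label "
                    f"{rec.label.value!r} (first seen as {seen[key]!r})"
                )
            seen.setdefault(key, rec.id)
            prev = by_seq.get(rec.sequence)
            if (
                not allow_conflicts
                and prev is not None
                and prev is not rec.label
                and Label.UNLABELED not in (prev, rec.label)
            ):
                raise PeptideIOError(
                    f"sequence {rec.sequence!r} carries conflicting labels "
                    f"{prev.value!r} and {rec.label.value!r}"
                )
            by_seq.setdefault(rec.sequence, rec.label)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PeptideRecord]:
        return iter(self.records)

    @property
    def class_sizes(self) -> dict[Label, int]:
        sizes: dict[Label, int] = {}
        for rec in self.records:
            sizes[rec.label] = sizes.get(rec.label, 0) + 1
        return sizes

    def subset(self, label: Label) -> "PeptideDataset":
        return PeptideDataset.from_records(
            [r for r in self.records if r.label is label], allow_duplicates=True
        )

    def sequences(self, label: Label | None = None) -> list[str]:
        return [
            r.sequence
            for r in self.records
            if label is None or r.label is label
        ]


# ---------------------------------------------------------------------------
# Dataset files
# ---------------------------------------------------------------------------

def read_peptides(
    path: str | Path,
    format: str | None = None,
    *,
    allow_duplicates: bool = False,
) -> PeptideDataset:
    """Read a labeled peptide dataset from TSV or FASTA.

    TSV rows are ``sequence<TAB>label``; FASTA description lines end in
    ``|label``. ``format`` is inferred from the file suffix when omitted
    (``.fa``/``.fasta`` -> fasta, anything else -> tsv). Records preserve
    file order; label tokens are case-insensitive and ``non-amyloid`` is
    accepted as an alias for ``non_amyloid``.
    """
    path = Path(path)
    if format is None:
        format = "fasta" if path.suffix.lower() in {".fa", ".fasta"} else "tsv"
    if format not in {"tsv", "fasta"}:
        raise ValueError(f"unknown dataset format {format!r}")

    records: list[PeptideRecord] = []
    if format == "tsv":
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise PeptideIOError(
                        f"{path}:{lineno}: expected 'sequence<TAB>label', "
                        f"got {line!r}"
                    )
                seq, token = parts[0].strip(), parts[1]
                try:
                    validate_sequence(seq)
                except ValidationError as exc:
                    raise PeptideIOError(f"{path}:{lineno}: {exc}") from exc
                records.append(
                    PeptideRecord(
                        id=f"{path.stem}:{lineno}",
                        sequence=seq,
                        label=Label.parse(token),
                    )
                )
    else:
        for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
            header = rec.description
            if "|" in header:
                ident, token = header.rsplit("|", 1)
                label = Label.parse(token)
            else:
                ident, label = header, Label.UNLABELED
            seq = str(rec.seq)
            try:
                validate_sequence(seq)
            except ValidationError as exc:
                raise PeptideIOError(
                    f"{path}: record {i} ({header!r}): {exc}"
                ) from exc
            records.append(
                PeptideRecord(id=ident.strip() or f"{path.stem}:{i}",
                              sequence=seq, label=label)
            )
    return PeptideDataset.from_records(records, allow_duplicates=allow_duplicates)


def write_peptides(
    dataset: PeptideDataset, path: str | Path, format: str = "tsv"
) -> None:
    """Write a dataset as TSV (``sequence<TAB>label``) or labeled FASTA."""
    path = Path(path)
    with open(path, "w") as fh:
        for rec in dataset:
            if format == "tsv":
                fh.write(f"{rec.sequence}\t{rec.label.value}\n")
            elif format == "fasta":
                fh.write(f">{rec.id}|{rec.label.value}\n{rec.sequence}\n")
            else:
                raise ValueError(f"unknown dataset format {format!r}")


def read_fasta_sequences(path: str | Path) -> list[tuple[str, str]]:
    """Read full-length protein sequences (id, sequence) for window scanning.

    Sequences may be any length >= 6; alphabet validation is applied.
    """
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper() if str(rec.seq).islower() else str(rec.seq)
        validate_sequence(seq, hexa=False)
        out.append((rec.id, seq))
    return out


# ---------------------------------------------------------------------------
# 20 x 6 matrix files
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a 20 x 6 value table keyed by one-letter residue code.

    The file is tab-separated with a header row of positions ``1..6`` and
    exactly one data row per residue; ``#`` lines are comments. The result
    is a DataFrame indexed by residue in canonical order with integer
    position columns 1..6. Missing/duplicate residues and non-numeric
    cells raise :class:`PeptideIOError`.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    first = df.columns[0]
    cols = list(df.columns[1:])
    if [str(c) for c in cols] != [str(j) for j in range(1, N_POSITIONS + 1)]:
        raise PeptideIOError(
            f"{path}: expected position columns 1..6, got {cols}"
        )
    residues = df[first].astype(str).str.strip()
    dup = residues[residues.duplicated()].tolist()
    if dup:
        raise PeptideIOError(f"{path}: duplicate residue row(s) {sorted(set(dup))}")
    unknown = sorted(set(residues) - set(AMINO_ACIDS))
    if unknown:
        raise PeptideIOError(f"{path}: unknown residue row(s) {unknown}")
    missing = sorted(set(AMINO_ACIDS) - set(residues))
    if missing:
        raise PeptideIOError(f"{path}: missing residue row(s) {missing}")
    try:
        values = df[cols].astype(float)
    except ValueError as exc:
        raise PeptideIOError(f"{path}: non-numeric cell: {exc}") from exc
    if values.isna().any().any():
        raise PeptideIOError(f"{path}: missing cell value")
    values.index = residues
    values.columns = range(1, N_POSITIONS + 1)
    return values.loc[list(AMINO_ACIDS)]


def write_matrix(
    values: pd.DataFrame | np.ndarray, path: str | Path, *, decimals: int = 3,
    comment: str | None = None,
) -> None:
    """Write a 20 x 6 table in the TSV dialect read by :func:`read_matrix`.

    Values are printed with ``decimals`` decimal places (3 by default, the
    precision of the published matrices), so write-then-read is the
    identity at that precision.
    """
    arr = np.asarray(values, dtype=float)
    if arr.shape != (N_RESIDUES, N_POSITIONS):
        raise ValueError(f"expected a 20x6 table, got shape {arr.shape}")
    with open(Path(path), "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("res\t" + "\t".join(str(j) for j in range(1, N_POSITIONS + 1)) + "\n")
        for i, aa in enumerate(AMINO_ACIDS):
            row = "\t".join(f"{arr[i, j]:.{decimals}f}" for j in range(N_POSITIONS))
            fh.write(f"{aa}\t{row}\n")


# ---------------------------------------------------------------------------
# Bundled reference data
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceComposition:
    """Background amino acid composition of globular proteins, in percent."""

    values: np.ndarray  # shape (20,), canonical residue order

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.shape != (N_RESIDUES,):
            raise ValueError("reference composition needs exactly 20 values")
        if not (arr > 0).all():
            raise ValueError("reference composition values must be positive")
        object.__setattr__(self, "values", arr)

    def __getitem__(self, residue: str) -> float:
        return float(self.values[RESIDUE_INDEX[residue]])

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(AMINO_ACIDS), name="percent")


def _data_path(name: str) -> Path:
    return Path(resources.files("amylpot.data") / name)


def load_reference_composition() -> ReferenceComposition:
    """Bundled globular-protein background composition (percent, 20 values)."""
    df = pd.read_csv(_data_path("globular_composition.tsv"), sep="\t", comment="#")
    series = df.set_index("res")["percent"]
    return ReferenceComposition(series.loc[list(AMINO_ACIDS)].to_numpy(float))


def load_amyloid_potentials():
    """Bundled published potential matrix for the amyloid class."""
    from .potentials import PotentialMatrix

    return PotentialMatrix.from_frame(read_matrix(_data_path("amyloid_potentials.tsv")))


def load_non_amyloid_potentials():
    """Bundled published potential matrix for the non-amyloid class."""
    from .potentials import PotentialMatrix

    return PotentialMatrix.from_frame(
        read_matrix(_data_path("non_amyloid_potentials.tsv"))
    )


def bundled_scale_path() -> Path:
    """Path of the shipped property-scale TSV (user-editable format)."""
    return _data_path("property_scales.tsv")
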