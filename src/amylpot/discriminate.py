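"""Scoring peptides with a pair of potential matrices and the sign rule.

A hexapeptide k is scored under both the amyloid-derived and the
non-amyloid-derived potential matrix by summing the position-specific
cell energies:

    phi_tot(k) = sum_{j=1..6} phi(r_j, j)

The discriminator is the difference

    delta_phi(k) = phi_tot(k | amyloid) - phi_tot(k | non-amyloid);

a negative value predicts amyloid-fibril formation (the peptide is more
stable under the amyloid statistics), otherwise — including an exact
tie — the peptide is predicted not to form fibrils.

The same scorer slides a 6-residue window along full-length protein
sequences to flag candidate aggregation-prone regions, and powers the
per-position energy-differential distributions used to contrast the two
classes around a cutoff (−0.2 kcal/mol in the published analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import (
    Label,
    N_POSITIONS,
    PeptideDataset,
    encode_sequence,
    validate_sequence,
)
from .ml import ConfusionCounts
from .potentials import PotentialMatrix


@dataclass(frozen=True)
class PeptideScore:
    """Total potentials of one hexapeptide under both matrices (kcal/mol)."""

    sequence: str
    phi_amyloid: float
    phi_nonamyloid: float

    @property
    def delta_phi(self) -> float:
        return self.phi_amyloid - self.phi_nonamyloid

    @property
    def call(self) -> Label:
        return Label.AMYLOID if self.delta_phi < 0 else Label.NON_AMYLOID


@dataclass(frozen=True)
class WindowScore:
    """Score of the hexapeptide window starting at 0-based ``start``."""

    start: int          # 0-based, half-open window [start, start+6)
    sequence: str
    score: PeptideScore

    @property
    def start1(self) -> int:
        """1-based start position, for display."""
        return self.start + 1

    @property
    def end(self) -> int:
        return self.start + N_POSITIONS


@dataclass(frozen=True)
class EnergyDistribution:
    """Per-class histogram of one position's energy differentials."""

    position: int
    bin_edges: np.ndarray
    class_frequencies: dict[Label, np.ndarray]
    cutoff: float
    cutoff_fractions: dict[Label, float]


def score_peptide(
    sequence: str, amy: PotentialMatrix, non: PotentialMatrix
) -> PeptideScore:
    """Score one hexapeptide under the amyloid and non-amyloid matrices."""
    validate_sequence(sequence)
    idx = encode_sequence(sequence)
    cols = np.arange(N_POSITIONS)
    return PeptideScore(
        sequence=sequence,
        phi_amyloid=float(amy.values[idx, cols].sum()),
        phi_nonamyloid=float(non.values[idx, cols].sum()),
    )


def score_dataset(
    dataset: PeptideDataset, amy: PotentialMatrix, non: PotentialMatrix
) -> list[PeptideScore]:
    return [score_peptide(rec.sequence, amy, non) for rec in dataset]


def classify_dataset(
    dataset: PeptideDataset, amy: PotentialMatrix, non: PotentialMatrix
) -> ConfusionCounts:
    """Confusion counts of the sign rule with amyloid as positive class."""
    tp = fp = tn = fn = 0
    for rec in dataset:
        if rec.label is Label.UNLABELED:
            raise ValueError(f"record {rec.id!r} is unlabeled")
        call = score_peptide(rec.sequence, amy, non).call
        if rec.label is Label.AMYLOID:
            if call is Label.AMYLOID:
                tp += 1
            else:
                fn += 1
        else:
            if call is Label.AMYLOID:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def scan_sequence(
    sequence: str,
    amy: PotentialMatrix,
    non: PotentialMatrix,
    step: int = 1,
) -> list[WindowScore]:
    """Score every 6-residue window of a protein sequence.

    Windows are reported in order of their 0-based start offsets
    0, step, 2*step, ... up to L-6 inclusive.
    """
    validate_sequence(sequence, hexa=False)
    if len(sequence) < N_POSITIONS:
        raise ValueError(
            f"sequence of length {len(sequence)} is shorter than a "
            f"{N_POSITIONS}-residue window"
        )
    if step < 1:
        raise ValueError("step must be >= 1")
    return [
        WindowScore(
            start=s,
            sequence=sequence[s : s + N_POSITIONS],
            score=score_peptide(sequence[s : s + N_POSITIONS], amy, non),
        )
        for s in range(0, len(sequence) - N_POSITIONS + 1, step)
    ]


def energy_differential_distribution(
    dataset: PeptideDataset,
    amy: PotentialMatrix,
    non: PotentialMatrix,
    position: int,
    bin_width: float = 0.2,
    cutoff: float = -0.2,
) -> EnergyDistribution:
    """Distribution of per-position energy differentials by class.

    For each peptide the differential at 1-based ``position`` j is
    ``phi_amy(r_j, j) - phi_non(r_j, j)``. Differentials are binned per
    class on a grid of width ``bin_width`` anchored at 0 (so the default
    cutoff −0.2 is a bin edge), and ``cutoff_fractions`` reports the
    per-class fraction of peptides with differential <= ``cutoff`` (the
    inclusive comparison keeps edge values in the favorable tail).
    """
    if not 1 <= position <= N_POSITIONS:
        raise ValueError(f"position must be in 1..{N_POSITIONS}")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    j = position - 1
    diffs: dict[Label, np.ndarray] = {}
    for label in (Label.AMYLOID, Label.NON_AMYLOID):
        seqs = dataset.sequences(label)
        if not seqs:
            raise ValueError(f"dataset has no records with label {label.value!r}")
        idx = np.array([encode_sequence(s)[j] for s in seqs], dtype=np.intp)
        diffs[label] = amy.values[idx, j] - non.values[idx, j]

    all_d = np.concatenate(list(diffs.values()))
    lo = bin_width * np.floor(all_d.min() / bin_width)
    hi = bin_width * np.ceil(all_d.max() / bin_width)
    if hi <= lo:
        hi = lo + bin_width
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    # keep the top edge inclusive so every value is binned
    edges[-1] = max(edges[-1], all_d.max())

    freqs = {
        label: np.histogram(d, bins=edges)[0] / d.size
        for label, d in diffs.items()
    }
    fracs = {label: float((d <= cutoff).mean()) for label, d in diffs.items()}
    return EnergyDistribution(
        position=position,
        bin_edges=edges,
        class_frequencies=freqs,
        cutoff=cutoff,
        cutoff_fractions=fracs,
    )
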