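"""Compositions, position-specific propensities and statistical potentials.

The method models a hexapeptide class (amyloid-fibril forming or not) by
the composition of residues at each of the six positions. Per position j
and residue i:

* composition              Comp(i,j) = 100 * n(i,j) / N(j)       [percent]
* propensity               Propen(i,j) = Comp(i,j) / Comp_glob(i)
* statistical potential    phi(i,j) = -RT * ln Propen(i,j)       [kcal/mol]

where Comp_glob is the background composition of globular proteins. A
propensity above 1 (negative potential) marks a residue favored at that
position in the class; the published matrices bundled with the package are
realized instances of this derivation at 3-decimal precision.

Residues never observed at a position have propensity 0, where the log is
undefined; such cells carry potential exactly 0.000 and are flagged
``observed=False`` so they can be told apart from true propensity-1 cells.
No pseudo-count is applied by default (matching the published matrices);
a configurable pseudo-count is available for derivations on small data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io import (
    AMINO_ACIDS,
    N_POSITIONS,
    N_RESIDUES,
    RESIDUE_INDEX,
    Label,
    PeptideDataset,
    ReferenceComposition,
    encode_sequence,
    load_reference_composition,
)

#: Default thermal constant RT in kcal/mol (~300 K). The published
#: preference thresholds (propensity 1.2 / 0.8) map to energies
#: -RT ln 1.2 = -0.109 and -RT ln 0.8 = +0.134 kcal/mol at this value.
RT_DEFAULT: float = 0.6


def _positions_frame(values: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        np.asarray(values, float),
        index=list(AMINO_ACIDS),
        columns=range(1, N_POSITIONS + 1),
    )


@dataclass(frozen=True)
class CompositionTable:
    """Overall residue composition of a peptide class, in percent."""

    values: np.ndarray  # (20,)
    n_total: int

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, float)
        if arr.shape != (N_RESIDUES,):
            raise ValueError("composition needs 20 values")
        if (arr < 0).any() or abs(arr.sum() - 100.0) > 1e-9:
            raise ValueError("composition must be non-negative and sum to 100")
        object.__setattr__(self, "values", arr)

    def __getitem__(self, residue: str) -> float:
        return float(self.values[RESIDUE_INDEX[residue]])

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(AMINO_ACIDS), name="percent")


@dataclass(frozen=True)
class PositionalCompositionMatrix:
    """Residue composition per hexapeptide position, in percent (20 x 6)."""

    values: np.ndarray        # (20, 6)
    n_per_position: np.ndarray  # (6,) peptide counts

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, float)
        npos = np.asarray(self.n_per_position, int)
        if arr.shape != (N_RESIDUES, N_POSITIONS) or npos.shape != (N_POSITIONS,):
            raise ValueError("expected 20x6 values and 6 position counts")
        if (arr < 0).any() or np.abs(arr.sum(axis=0) - 100.0).max() > 1e-9:
            raise ValueError("each position column must sum to 100")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "n_per_position", npos)

    def as_frame(self) -> pd.DataFrame:
        return _positions_frame(self.values)


@dataclass(frozen=True)
class PropensityMatrix:
    """Position-specific propensities Comp(i,j)/Comp_glob(i) (20 x 6)."""

    values: np.ndarray   # (20, 6), dimensionless, >= 0
    observed: np.ndarray  # (20, 6) bool, nonzero underlying counts

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, float)
        obs = np.asarray(self.observed, bool)
        if arr.shape != (N_RESIDUES, N_POSITIONS) or obs.shape != arr.shape:
            raise ValueError("expected 20x6 propensities and observed flags")
        if (arr < 0).any():
            raise ValueError("propensities must be non-negative")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "observed", obs)

    def as_frame(self) -> pd.DataFrame:
        return _positions_frame(self.values)


@dataclass(frozen=True)
class PotentialMatrix:
    """Statistical potentials phi(i,j) = -RT ln Propen(i,j), kcal/mol (20 x 6).

    Cells with ``observed=False`` (zero underlying count) hold exactly
    0.000 and contribute nothing to peptide scores.
    """

    values: np.ndarray   # (20, 6), kcal/mol
    rt: float = RT_DEFAULT
    observed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, float)
        if arr.shape != (N_RESIDUES, N_POSITIONS):
            raise ValueError("expected a 20x6 potential table")
        if not np.isfinite(arr).all():
            raise ValueError("potentials must be finite")
        if self.rt <= 0:
            raise ValueError("rt must be positive")
        obs = self.observed
        if obs is None:
            # Printed matrices carry no explicit flags: a cell that is
            # exactly zero is taken as unobserved (see package docs).
            obs = arr != 0.0
        obs = np.asarray(obs, bool)
        if obs.shape != arr.shape:
            raise ValueError("observed flags must be 20x6")
        if not (arr[~obs] == 0.0).all():
            raise ValueError("unobserved cells must hold exactly 0.0")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "observed", obs)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, rt: float = RT_DEFAULT) -> "PotentialMatrix":
        return cls(values=frame.to_numpy(float), rt=rt)

    def as_frame(self) -> pd.DataFrame:
        return _positions_frame(self.values)

    def cell(self, residue: str, position: int) -> float:
        """phi for ``residue`` at 1-based ``position``."""
        return float(self.values[RESIDUE_INDEX[residue], position - 1])


@dataclass(frozen=True)
class PreferenceThresholds:
    """Propensity cutoffs for calling residues preferred/avoided."""

    preferred_min: float = 1.2
    avoided_max: float = 0.8

    def __post_init__(self) -> None:
        if not self.preferred_min > self.avoided_max > 0:
            raise ValueError("need preferred_min > avoided_max > 0")


# ---------------------------------------------------------------------------
# Derivation operations
# ---------------------------------------------------------------------------

def _class_sequences(dataset: PeptideDataset, label: Label) -> list[str]:
    seqs = dataset.sequences(label)
    if not seqs:
        raise ValueError(f"dataset has no records with label {label.value!r}")
    return seqs


def _position_counts(sequences: list[str]) -> np.ndarray:
    idx = np.array([encode_sequence(s) for s in sequences], dtype=np.intp)
    counts = np.zeros((N_RESIDUES, N_POSITIONS), dtype=np.int64)
    for j in range(N_POSITIONS):
        counts[:, j] = np.bincount(idx[:, j], minlength=N_RESIDUES)
    return counts


def overall_composition(dataset: PeptideDataset, label: Label) -> CompositionTable:
    """Overall percent composition over all residues of all class peptides."""
    seqs = _class_sequences(dataset, label)
    counts = _position_counts(seqs).sum(axis=1)
    n = int(counts.sum())
    return CompositionTable(values=100.0 * counts / n, n_total=n)


def positional_composition(
    dataset: PeptideDataset, label: Label
) -> PositionalCompositionMatrix:
    """Percent composition per position; denominator is the peptide count."""
    seqs = _class_sequences(dataset, label)
    counts = _position_counts(seqs)
    n = len(seqs)
    return PositionalCompositionMatrix(
        values=100.0 * counts / n,
        n_per_position=np.full(N_POSITIONS, n, dtype=int),
    )


def positional_propensity(
    pos: PositionalCompositionMatrix,
    ref: ReferenceComposition | None = None,
    *,
    pseudo: float = 0.0,
) -> PropensityMatrix:
    """Normalize positional composition by the background composition.

    ``pseudo`` adds a per-cell pseudo-count (in peptides) before
    normalization; the default 0 matches the published matrices. With a
    pseudo-count every cell is treated as observed.
    """
    if ref is None:
        ref = load_reference_composition()
    if pseudo < 0:
        raise ValueError("pseudo-count must be non-negative")
    comp = pos.values
    if pseudo > 0:
        n = pos.n_per_position.astype(float)
        counts = comp * n / 100.0 + pseudo
        comp = 100.0 * counts / counts.sum(axis=0, keepdims=True)
    values = comp / ref.values[:, None]
    return PropensityMatrix(values=values, observed=comp > 0)


def propensity_to_potential(
    prop: PropensityMatrix, rt: float = RT_DEFAULT
) -> PotentialMatrix:
    """Boltzmann-invert propensities into potentials, -RT ln Propen.

    Unobserved cells (propensity 0) get exactly 0.000 with the flag
    propagated.
    """
    if rt <= 0:
        raise ValueError("rt must be positive")
    values = np.zeros_like(prop.values)
    obs = prop.observed & (prop.values > 0)
    values[obs] = -rt * np.log(prop.values[obs])
    return PotentialMatrix(values=values, rt=rt, observed=obs)


def potential_to_propensity(pot: PotentialMatrix) -> PropensityMatrix:
    """Invert a potential matrix back to propensities (exp(-phi/RT)).

    Unobserved cells map back to propensity 0 with ``observed=False``.
    """
    values = np.where(pot.observed, np.exp(-pot.values / pot.rt), 0.0)
    return PropensityMatrix(values=values, observed=pot.observed.copy())


def derive_potentials(
    dataset: PeptideDataset,
    label: Label,
    ref: ReferenceComposition | None = None,
    rt: float = RT_DEFAULT,
    *,
    pseudo: float = 0.0,
) -> PotentialMatrix:
    """Full derivation pipeline: dataset class -> potential matrix."""
    pos = positional_composition(dataset, label)
    prop = positional_propensity(pos, ref, pseudo=pseudo)
    return propensity_to_potential(prop, rt)


def classify_preferences(
    prop: PropensityMatrix,
    thresholds: PreferenceThresholds | None = None,
) -> dict[int, dict[str, set[str]]]:
    """Per-position preferred and avoided residue sets.

    A residue is *preferred* at a position when it is observed there with
    propensity >= ``preferred_min`` (default 1.2) and *avoided* when its
    propensity is <= ``avoided_max`` (default 0.8) — unobserved residues
    (propensity 0) count as avoided.
    """
    th = thresholds or PreferenceThresholds()
    out: dict[int, dict[str, set[str]]] = {}
    for j in range(N_POSITIONS):
        col = prop.values[:, j]
        obs = prop.observed[:, j]
        preferred = {AMINO_ACIDS[i] for i in range(N_RESIDUES)
                     if obs[i] and col[i] >= th.preferred_min}
        avoided = {AMINO_ACIDS[i] for i in range(N_RESIDUES)
                   if col[i] <= th.avoided_max}
        out[j + 1] = {"preferred": preferred, "avoided": avoided}
    return out
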