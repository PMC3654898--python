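"""Per-residue property scales and total-property computations.

Each scale assigns one numeric value to each of the 20 residues; the
total property of a hexapeptide is the sum of its six residue values,

    P_total = sum_{j=1..6} P(r_j).

The shipped scale file provides the RPLC retention-time hydrophobicity
coefficients (whose hexapeptide total is the total hydrophobicity H_T),
an isoelectric-point scale, a clearly-labelled synthetic stand-in for a
long-range non-bonded energy scale, and placeholder rows for a wider
property compilation that users may fill in. Only scales with a complete
set of 20 values are usable for computation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import (
    AMINO_ACIDS,
    Label,
    N_RESIDUES,
    PeptideDataset,
    RESIDUE_INDEX,
    bundled_scale_path,
    validate_sequence,
)

#: Name of the bundled hydrophobicity scale (H_T = its hexapeptide total).
MANT_HYDROPHOBICITY = "mant_hydrophobicity"

#: Default property triple used by the ML feature vector.
DEFAULT_PROPERTY_SCALES = (
    MANT_HYDROPHOBICITY,
    "isoelectric_point",
    "long_range_energy_synthetic",
)


@dataclass(frozen=True)
class PropertyScale:
    """A named per-residue scale with exactly 20 values."""

    name: str
    values: np.ndarray  # (20,), canonical residue order
    description: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, float)
        if arr.shape != (N_RESIDUES,):
            raise ValueError(
                f"scale {self.name!r} needs exactly {N_RESIDUES} values"
            )
        if not np.isfinite(arr).all():
            raise ValueError(f"scale {self.name!r} has non-finite values")
        object.__setattr__(self, "values", arr)

    def __getitem__(self, residue: str) -> float:
        try:
            return float(self.values[RESIDUE_INDEX[residue]])
        except KeyError:
            raise KeyError(
                f"residue {residue!r} missing from scale {self.name!r}"
            ) from None


@dataclass(frozen=True)
class PropertyTotal:
    peptide_id: str
    scale_name: str
    total: float


@dataclass(frozen=True)
class PropertySummary:
    """Per-class mean/sd of a scale's hexapeptide totals."""

    scale_name: str
    mean_amyloid: float
    mean_nonamyloid: float
    sd_amyloid: float
    sd_nonamyloid: float

    @property
    def difference(self) -> float:
        return self.mean_amyloid - self.mean_nonamyloid


class ScaleRegistry:
    """Registry of property scales loaded from the editable TSV file.

    The file format is one row per scale: ``scale``, ``description``,
    ``units``, then 20 value columns A..Y. Rows with missing values are
    kept as placeholders: they appear in :meth:`names` but raise on
    :meth:`get`.
    """

    def __init__(self) -> None:
        self._scales: dict[str, PropertyScale] = {}
        self._placeholders: dict[str, str] = {}

    @classmethod
    def from_file(cls, path: str | Path | None = None) -> "ScaleRegistry":
        path = Path(path) if path is not None else bundled_scale_path()
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        required = ["scale", "description", "units", *AMINO_ACIDS]
        if list(df.columns) != required:
            raise ValueError(
                f"{path}: expected columns {required}, got {list(df.columns)}"
            )
        reg = cls()
        for _, row in df.iterrows():
            name = str(row["scale"]).strip()
            raw = row[list(AMINO_ACIDS)]
            if raw.isna().any():
                reg._placeholders[name] = str(row["description"] or "")
                continue
            reg.add(
                PropertyScale(
                    name=name,
                    values=raw.astype(float).to_numpy(),
                    description=str(row["description"] or ""),
                    units=str(row["units"] or ""),
                )
            )
        return reg

    def add(self, scale: PropertyScale) -> None:
        self._scales[scale.name] = scale

    def get(self, name: str) -> PropertyScale:
        if name in self._scales:
            return self._scales[name]
        if name in self._placeholders:
            raise KeyError(
                f"scale {name!r} is a placeholder without values; edit the "
                "scale file to use it"
            )
        raise KeyError(f"unknown scale {name!r}")

    def names(self, *, complete_only: bool = False) -> list[str]:
        names = list(self._scales)
        if not complete_only:
            names += list(self._placeholders)
        return names

    def __contains__(self, name: str) -> bool:
        return name in self._scales or name in self._placeholders


_default_registry: ScaleRegistry | None = None


def default_registry() -> ScaleRegistry:
    """The registry loaded from the bundled scale file (cached)."""
    global _default_registry
    if _default_registry is None:
        _default_registry = ScaleRegistry.from_file()
    return _default_registry


def load_mant_scale() -> PropertyScale:
    """The bundled RPLC retention-time hydrophobicity coefficients."""
    return default_registry().get(MANT_HYDROPHOBICITY)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def total_property(sequence: str, scale: PropertyScale,
                   peptide_id: str | None = None) -> PropertyTotal:
    """Sum of the scale values of a hexapeptide's six residues."""
    validate_sequence(sequence)
    total = float(sum(scale[c] for c in sequence))
    return PropertyTotal(
        peptide_id=peptide_id if peptide_id is not None else sequence,
        scale_name=scale.name,
        total=total,
    )


def total_hydrophobicity(sequence: str) -> float:
    """H_T: total of the bundled hydrophobicity coefficients."""
    return total_property(sequence, load_mant_scale()).total


def _class_totals(dataset: PeptideDataset, scale: PropertyScale,
                  label: Label) -> np.ndarray:
    seqs = dataset.sequences(label)
    if not seqs:
        raise ValueError(f"dataset has no records with label {label.value!r}")
    return np.array([total_property(s, scale).total for s in seqs])


def class_property_summary(
    dataset: PeptideDataset,
    scales: list[PropertyScale] | PropertyScale,
    *,
    ddof: int = 1,
) -> list[PropertySummary]:
    """Per-scale class means and standard deviations of peptide totals.

    Sample standard deviation (ddof=1) is the default convention; a class
    of size 1 reports sd 0.
    """
    if isinstance(scales, PropertyScale):
        scales = [scales]
    if not scales:
        raise ValueError("need at least one scale")
    out = []
    for scale in scales:
        amy = _class_totals(dataset, scale, Label.AMYLOID)
        non = _class_totals(dataset, scale, Label.NON_AMYLOID)
        out.append(
            PropertySummary(
                scale_name=scale.name,
                mean_amyloid=float(amy.mean()),
                mean_nonamyloid=float(non.mean()),
                sd_amyloid=float(amy.std(ddof=ddof)) if amy.size > ddof else 0.0,
                sd_nonamyloid=float(non.std(ddof=ddof)) if non.size > ddof else 0.0,
            )
        )
    return out


def hydrophobicity_histogram(
    dataset: PeptideDataset,
    bin_width: float = 50.0,
    *,
    origin: float = 0.0,
    scale: PropertyScale | None = None,
) -> tuple[np.ndarray, dict[Label, np.ndarray]]:
    """Per-class binned frequencies of total hydrophobicity H_T.

    Bins have width ``bin_width`` on a grid anchored at ``origin``
    (half-open [lo, hi) except the last bin, which includes its upper
    edge). Returns ``(bin_edges, {label: frequencies})`` with per-class
    frequencies summing to 1.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    scale = scale or load_mant_scale()
    totals = {
        label: _class_totals(dataset, scale, label)
        for label in (Label.AMYLOID, Label.NON_AMYLOID)
    }
    all_t = np.concatenate(list(totals.values()))
    lo = origin + bin_width * np.floor((all_t.min() - origin) / bin_width)
    hi = origin + bin_width * np.ceil((all_t.max() - origin) / bin_width)
    if hi <= lo:
        hi = lo + bin_width
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    freqs = {
        label: np.histogram(t, bins=edges)[0] / t.size
        for label, t in totals.items()
    }
    return edges, freqs


def class_profile(
    summaries: list[PropertySummary], label: Label = Label.AMYLOID
) -> np.ndarray:
    """Vector of one class's per-scale means, in summary order."""
    if label is Label.AMYLOID:
        return np.array([s.mean_amyloid for s in summaries])
    if label is Label.NON_AMYLOID:
        return np.array([s.mean_nonamyloid for s in summaries])
    raise ValueError("profile class must be amyloid or non_amyloid")


def compare_property_profiles(
    a: list[PropertySummary],
    b: list[PropertySummary],
    *,
    class_a: Label = Label.AMYLOID,
    class_b: Label = Label.AMYLOID,
) -> tuple[float, float]:
    """Agreement between two per-scale mean profiles.

    ``a`` and ``b`` must cover the same scales in the same order; the
    chosen class's means are paired scale by scale. To contrast the two
    classes of a single dataset (the within-study comparison), pass the
    same summaries twice with ``class_b=Label.NON_AMYLOID``. Returns
    ``(pearson_r, chi_square)`` where the chi-square statistic is
    ``sum((a_i - b_i)^2 / |b_i|)`` over the paired means.
    """
    names_a = [s.scale_name for s in a]
    names_b = [s.scale_name for s in b]
    if names_a != names_b:
        raise ValueError("summary sets cover different scales")
    if len(a) < 2:
        raise ValueError("need at least two scales to correlate")
    x = class_profile(a, class_a)
    y = class_profile(b, class_b)
    if np.allclose(x, y):
        r = 1.0
    else:
        r = float(stats.pearsonr(x, y).statistic)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (x - y) ** 2 / np.abs(y)
    chi2 = float(np.nansum(terms[np.isfinite(terms)]))
    return r, chi2
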