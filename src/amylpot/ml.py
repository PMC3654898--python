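"""Feature construction, metrics and cross-validated ensemble evaluation.

Each hexapeptide maps to a fixed feature vector: the six position-specific
energies under the amyloid matrix, the six under the non-amyloid matrix,
and (by default) three property totals — hydrophobicity, isoelectric
point, and a long-range non-bonded energy stand-in — for 15 features. An
energy-only 12-feature mode and a 6-feature per-position energy-difference
mode are also available.

The learner is a bagged randomized-decision-tree ensemble (random forest:
100 trees, unlimited depth, sqrt(p) features per split) evaluated by
stratified k-fold cross-validation; metrics are computed from confusion
counts pooled over all folds, with the amyloid class positive:

    sensitivity = TP/(TP+FN)
    specificity = TN/(TN+FP)
    accuracy    = (TP+TN)/(TP+TN+FP+FN)
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, KFold

from .io import Label, N_POSITIONS, PeptideDataset, encode_sequence, validate_sequence
from .potentials import PotentialMatrix
from .properties import (
    DEFAULT_PROPERTY_SCALES,
    PropertyScale,
    default_registry,
    total_property,
)

#: Feature-set modes.
FEATURES_FULL = "energies+props"
FEATURES_ENERGY = "energies"
FEATURES_DELTA = "delta"


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN with the amyloid class as positive."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            tp=self.tp + other.tp,
            fp=self.fp + other.fp,
            tn=self.tn + other.tn,
            fn=self.fn + other.fn,
        )


@dataclass(frozen=True)
class Metrics:
    sensitivity: float
    specificity: float
    accuracy: float


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero for the given counts."""


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    """Sensitivity, specificity and accuracy from confusion counts.

    Ratios are formed in exact rational arithmetic before the final float
    conversion; a zero denominator raises :class:`UndefinedMetricError`
    rather than silently reporting 0.
    """
    if counts.tp + counts.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive records")
    if counts.tn + counts.fp == 0:
        raise UndefinedMetricError("specificity undefined: no negative records")
    if counts.total == 0:
        raise UndefinedMetricError("accuracy undefined: empty counts")
    sens = Fraction(counts.tp, counts.tp + counts.fn)
    spec = Fraction(counts.tn, counts.tn + counts.fp)
    acc = Fraction(counts.tp + counts.tn, counts.total)
    return Metrics(
        sensitivity=float(sens), specificity=float(spec), accuracy=float(acc)
    )


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------

def feature_names(
    mode: str = FEATURES_FULL,
    scale_names: tuple[str, ...] = DEFAULT_PROPERTY_SCALES,
) -> list[str]:
    energy = [f"phi_amy_{j}" for j in range(1, N_POSITIONS + 1)] + [
        f"phi_non_{j}" for j in range(1, N_POSITIONS + 1)
    ]
    if mode == FEATURES_ENERGY:
        return energy
    if mode == FEATURES_FULL:
        return energy + [f"total_{name}" for name in scale_names]
    if mode == FEATURES_DELTA:
        return [f"delta_phi_{j}" for j in range(1, N_POSITIONS + 1)]
    raise ValueError(f"unknown feature mode {mode!r}")


def _resolve_scales(
    scales: tuple[str, ...] | list[PropertyScale] | None,
) -> list[PropertyScale]:
    if scales is None:
        scales = DEFAULT_PROPERTY_SCALES
    out = []
    for s in scales:
        out.append(default_registry().get(s) if isinstance(s, str) else s)
    return out


def build_features(
    sequence: str,
    amy: PotentialMatrix,
    non: PotentialMatrix,
    scales: tuple[str, ...] | list[PropertyScale] | None = None,
    *,
    mode: str = FEATURES_FULL,
) -> np.ndarray:
    """Deterministic feature vector for one hexapeptide.

    Full mode: 12 per-position energies (amyloid then non-amyloid matrix)
    followed by one total per property scale. ``mode=FEATURES_ENERGY``
    drops the property totals; ``mode=FEATURES_DELTA`` uses the six
    per-position energy differences instead.
    """
    validate_sequence(sequence)
    idx = encode_sequence(sequence)
    cols = np.arange(N_POSITIONS)
    e_amy = amy.values[idx, cols]
    e_non = non.values[idx, cols]
    if mode == FEATURES_DELTA:
        return e_amy - e_non
    if mode == FEATURES_ENERGY:
        return np.concatenate([e_amy, e_non])
    if mode != FEATURES_FULL:
        raise ValueError(f"unknown feature mode {mode!r}")
    totals = [total_property(sequence, s).total for s in _resolve_scales(scales)]
    return np.concatenate([e_amy, e_non, np.asarray(totals)])


def build_feature_table(
    dataset: PeptideDataset,
    amy: PotentialMatrix,
    non: PotentialMatrix,
    scales: tuple[str, ...] | list[PropertyScale] | None = None,
    *,
    mode: str = FEATURES_FULL,
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix X and binary label vector y (1 = amyloid)."""
    rows, y = [], []
    for rec in dataset:
        if rec.label is Label.UNLABELED:
            raise ValueError(f"record {rec.id!r} is unlabeled")
        rows.append(build_features(rec.sequence, amy, non, scales, mode=mode))
        y.append(1 if rec.label is Label.AMYLOID else 0)
    return np.vstack(rows), np.asarray(y, dtype=int)


# ---------------------------------------------------------------------------
# Learner and cross-validation
# ---------------------------------------------------------------------------

def train_ensemble(
    X: np.ndarray,
    y: np.ndarray,
    seed: int = 0,
    *,
    n_trees: int = 100,
) -> RandomForestClassifier:
    """Fit the randomized-tree ensemble (majority-vote prediction)."""
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    model = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        max_depth=None,
        random_state=seed,
    )
    model.fit(X, y)
    return model


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation settings (5/10/20 folds in the published protocol)."""

    n_folds: int = 10
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


@dataclass(frozen=True)
class CVResult:
    fold_counts: tuple[ConfusionCounts, ...]
    pooled: ConfusionCounts
    metrics: Metrics
    test_indices: tuple[np.ndarray, ...]


def _counts_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray
) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def cross_validate(
    dataset: PeptideDataset,
    amy: PotentialMatrix,
    non: PotentialMatrix,
    config: CVConfig | None = None,
    scales: tuple[str, ...] | list[PropertyScale] | None = None,
    *,
    mode: str = FEATURES_FULL,
    n_trees: int = 100,
) -> CVResult:
    """Stratified k-fold cross-validation of the tree ensemble.

    Every record is tested exactly once; metrics come from confusion
    counts pooled across folds. Fold assignment and forest training are
    deterministic given ``config.seed``.
    """
    cfg = config or CVConfig()
    X, y = build_feature_table(dataset, amy, non, scales, mode=mode)
    if cfg.n_folds > len(y):
        raise ValueError("n_folds exceeds dataset size")
    if cfg.stratified:
        if cfg.n_folds > min(np.bincount(y, minlength=2)):
            raise ValueError("n_folds exceeds the size of the smaller class")
        splitter = StratifiedKFold(
            n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed
        )
    else:
        splitter = KFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)

    fold_counts: list[ConfusionCounts] = []
    test_idx: list[np.ndarray] = []
    for k, (train, test) in enumerate(splitter.split(X, y)):
        model = train_ensemble(X[train], y[train], seed=cfg.seed + k,
                               n_trees=n_trees)
        fold_counts.append(_counts_from_predictions(y[test], model.predict(X[test])))
        test_idx.append(test)
    pooled = fold_counts[0]
    for c in fold_counts[1:]:
        pooled = pooled + c
    return CVResult(
        fold_counts=tuple(fold_counts),
        pooled=pooled,
        metrics=compute_metrics(pooled),
        test_indices=tuple(test_idx),
    )
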