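"""Record cleaning, threshold binarization, normalization and splits.

The dependent variable of every model in this package is an *exceedance*
indicator: 1 iff a well's arsenic concentration is strictly greater than a
threshold, 0 otherwise (a value exactly equal to the threshold is low).
Binary datasets are built at a ladder of thresholds — by default 10, 5, 4,
3, 2 and 1 µg/L — and split 80/20 with per-class stratification so that
train and test preserve the low/high ratio of the full dataset.

Covariates are z-scored once on the full cleaned dataset (not per split) so
that coefficients averaged over many resampled fits share a single scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import PredictorStack

DEFAULT_THRESHOLDS = (10.0, 5.0, 4.0, 3.0, 2.0, 1.0)


class DegenerateFeatureError(ValueError):
    """A feature is constant and cannot be z-scored."""


class StratificationError(ValueError):
    """Labels contain a single class; a stratified split is impossible."""


@dataclass(frozen=True)
class CleanReport:
    table: pd.DataFrame
    n_not_analysed: int
    n_missing_location: int


@dataclass(frozen=True)
class NormalizationStats:
    names: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray

    def to_dict(self) -> dict:
        return {
            name: {"mean": float(m), "sd": float(s)}
            for name, m, s in zip(self.names, self.mean, self.sd)
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationStats":
        names = tuple(d)
        return cls(
            names,
            np.array([d[n]["mean"] for n in names]),
            np.array([d[n]["sd"] for n in names]),
        )


@dataclass(frozen=True)
class BinaryDataset:
    """Normalized feature matrix with exceedance labels per threshold."""

    features: np.ndarray  # n × p, z-scored
    feature_names: tuple[str, ...]
    feature_kinds: dict[str, str]  # 'continuous' | 'categorical'
    labels: dict[float, np.ndarray]  # threshold → {0,1}ⁿ
    norm_stats: NormalizationStats
    concentrations: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.features.shape[0]

    def columns(self, names) -> np.ndarray:
        idx = [self.feature_names.index(n) for n in names]
        return self.features[:, idx]


@dataclass(frozen=True)
class SplitPair:
    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int
    threshold: float | None = None


def exclude_invalid(wells: pd.DataFrame) -> CleanReport:
    """Drop not-analysed records and records without location.

    ``not_analysed`` (truthy) marks concentrations recorded as missing-by-
    assay; ``missing_location`` marks records lacking coordinates.  Row
    order of survivors is preserved.
    """
    df = wells
    na = df["not_analysed"].astype(bool) if "not_analysed" in df else pd.Series(False, index=df.index)
    ml = df["missing_location"].astype(bool) if "missing_location" in df else pd.Series(False, index=df.index)
    # a record failing both checks counts as not-analysed, matching the
    # order the survey applied its exclusions
    n_na = int(na.sum())
    n_ml = int((ml & ~na).sum())
    kept = df.loc[~na & ~ml].reset_index(drop=True)
    return CleanReport(kept, n_na, n_ml)


def binarize(concentrations, threshold: float) -> np.ndarray:
    """1 iff concentration is strictly above the threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    c = np.asarray(concentrations, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    return (c > threshold).astype(int)


def normalize(
    matrix, stats: NormalizationStats | None = None, names=None
) -> tuple[np.ndarray, NormalizationStats]:
    """Z-score columns; reuse supplied stats on the prediction path.

    When ``stats`` is given it is applied as-is (never re-estimated), which
    is what a prediction grid needs.  A constant column without supplied
    stats raises :class:`DegenerateFeatureError` naming the offenders.
    """
    X = np.asarray(matrix, dtype=float)
    if names is None:
        names = tuple(f"x{i}" for i in range(X.shape[1]))
    names = tuple(names)
    if stats is None:
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        bad = [n for n, s in zip(names, sd) if s == 0]
        if bad:
            raise DegenerateFeatureError(f"constant features: {bad}")
        stats = NormalizationStats(names, mean, sd)
    else:
        if stats.names != names:
            raise ValueError("normalization stats do not match feature names")
    return (X - stats.mean) / stats.sd, stats


def denormalize(Z, stats: NormalizationStats) -> np.ndarray:
    return np.asarray(Z, dtype=float) * stats.sd + stats.mean


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def stratified_split(
    labels, train_fraction: float = 0.8, seed: int = 0, threshold: float | None = None
) -> SplitPair:
    """Per-class random partition preserving the class ratio.

    The train count within each class is the class size times
    ``train_fraction`` rounded to the nearest integer (ties up), so the
    positive-class proportion of train and test each sit within one
    record's worth of the full-data proportion.  Deterministic per seed.
    """
    y = np.asarray(labels, dtype=int)
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    classes = np.unique(y)
    if classes.size < 2:
        raise StratificationError("both classes must be present")
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for cls in classes:
        idx = np.flatnonzero(y == cls)
        n_train = _round_half_up(train_fraction * idx.size)
        n_train = min(max(n_train, 1), idx.size - 1)  # keep both sides non-empty
        perm = rng.permutation(idx)
        train_parts.append(perm[:n_train])
        test_parts.append(perm[n_train:])
    return SplitPair(
        np.sort(np.concatenate(train_parts)),
        np.sort(np.concatenate(test_parts)),
        seed,
        threshold,
    )


def extract_covariates(stack: PredictorStack, wells: pd.DataFrame) -> pd.DataFrame:
    """Predictor values at each well's cell (wells on nodata cells dropped)."""
    rows, cols = stack.geometry.cell_of(wells["x"].to_numpy(), wells["y"].to_numpy())
    ok = ~stack.nodata_mask[rows, cols]
    feats = stack.values_at(rows[ok], cols[ok])
    feats.index = wells.index[ok]
    return feats


def build_dataset(
    stack: PredictorStack,
    wells: pd.DataFrame,
    thresholds=DEFAULT_THRESHOLDS,
) -> BinaryDataset:
    """Assemble the normalized feature matrix and per-threshold labels."""
    feats = extract_covariates(stack, wells)
    conc = wells.loc[feats.index, "as_ugL"].to_numpy(dtype=float)
    X, stats = normalize(feats.to_numpy(), names=tuple(feats.columns))
    labels = {float(t): binarize(conc, float(t)) for t in thresholds}
    return BinaryDataset(
        features=X,
        feature_names=tuple(feats.columns),
        feature_kinds=dict(stack.layer_kind),
        labels=labels,
        norm_stats=stats,
        concentrations=conc,
    )
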