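"""Probability grids, cutoff calibration and the pseudo-contour band map.

Each final exceedance model is evaluated over the predictor stack to give a
probability grid.  Classification cutoffs are calibrated where sensitivity
equals specificity (sweeping a fine cutoff grid and interpolating at the
first sign change), each probability grid is thresholded at its cutoff into
a binary exceedance map, and the per-threshold maps are stacked into an
ordinal pseudo-contour map of concentration bands: a cell exceeding the
5 µg/L map but not the 10 µg/L map falls in the 5–10 µg/L band, and so on.
Cells violating the expected nesting of exceedance maps are flagged and
resolved by the highest exceeded threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special

from .ensemble import FinalModel
from .grids import GeometryError, GridGeometry
from .preprocess import NormalizationStats
from .synthetic import PredictorStack

#: Thresholds combined into the default band map; the lowest modelled
#: threshold (1 µg/L) is excluded because its classifier is barely better
#: than chance at the assay's detection limit.
MAP_THRESHOLDS = (2.0, 3.0, 4.0, 5.0, 10.0)


@dataclass(frozen=True)
class CutoffAnalysis:
    """Sensitivity/specificity/accuracy swept over a cutoff grid."""

    cutoffs: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    accuracy: np.ndarray


@dataclass(frozen=True)
class BandMap:
    """Ordinal concentration-band grid combined from exceedance maps.

    ``bands`` holds indices into ``labels`` (−1 for nodata); band 0 is
    below the lowest threshold, the top band above the highest.
    """

    bands: np.ndarray  # int grid, −1 nodata
    labels: tuple[str, ...]
    thresholds: tuple[float, ...]
    cutoffs: dict[float, float]
    inconsistency_mask: np.ndarray
    geometry: GridGeometry


def probability_grid(
    model: FinalModel,
    stack: PredictorStack,
    norm_stats: NormalizationStats,
) -> np.ndarray:
    """Per-cell logistic probability under the final model.

    Stack layers are z-scored with the *stored* training statistics before
    applying the coefficients (they are on the normalized scale).  Nodata
    cells propagate as NaN.
    """
    missing = [v for v in model.variables if v not in stack.layers]
    if missing:
        raise KeyError(f"stack is missing model layers: {missing}")
    stat = {n: (m, s) for n, m, s in zip(norm_stats.names, norm_stats.mean, norm_stats.sd)}
    lin = np.full(stack.geometry.shape, model.intercept, dtype=float)
    for name, beta in zip(model.variables, model.coefficients):
        if name not in stat:
            raise KeyError(f"no normalization stats for layer {name!r}")
        mean, sd = stat[name]
        lin += beta * (stack.layers[name] - mean) / sd
    probs = special.expit(lin)
    probs[stack.nodata_mask] = np.nan
    return probs


def cutoff_curves(probs, y, grid_step: float = 0.001) -> CutoffAnalysis:
    """Sweep sensitivity, specificity and accuracy over a cutoff grid.

    Classification at cutoff c is positive iff probability ≥ c, so cutoff 0
    yields sensitivity exactly 1 and specificity exactly 0.
    """
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    cutoffs = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    pos = np.sort(probs[y == 1])
    neg = np.sort(probs[y == 0])
    tp = pos.size - np.searchsorted(pos, cutoffs, side="left")
    fp = neg.size - np.searchsorted(neg, cutoffs, side="left")
    sens = tp / pos.size
    spec = (neg.size - fp) / neg.size
    acc = (tp + neg.size - fp) / (pos.size + neg.size)
    return CutoffAnalysis(cutoffs, sens, spec, acc)


def crossover_cutoff(analysis: CutoffAnalysis) -> float:
    """Cutoff where sensitivity equals specificity.

    Finds the first sign change of (sensitivity − specificity) along the
    cutoff grid and interpolates linearly between the bracketing grid
    points; an exact zero on a grid point returns that point.  If the
    difference never changes sign the boundary cutoff is returned with a
    warning.
    """
    d = analysis.sensitivity - analysis.specificity
    c = analysis.cutoffs
    if d[0] < 0:
        warnings.warn("sensitivity below specificity at cutoff 0", UserWarning)
    for i in range(d.size):
        if d[i] == 0.0:
            return float(c[i])
        if i + 1 < d.size and d[i] > 0 > d[i + 1]:
            frac = d[i] / (d[i] - d[i + 1])
            return float(c[i] + frac * (c[i + 1] - c[i]))
    warnings.warn("sensitivity - specificity never changes sign", UserWarning)
    return float(c[-1] if d[-1] > 0 else c[0])


def exceedance_grid(probs: np.ndarray, cutoff: float) -> np.ndarray:
    """Binary exceedance map: 1 iff probability ≥ cutoff (NaN propagates)."""
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must be in [0, 1]")
    probs = np.asarray(probs, dtype=float)
    out = np.where(np.isnan(probs), np.nan, (probs >= cutoff).astype(float))
    return out


def band_labels(thresholds) -> tuple[str, ...]:
    t = [f"{x:g}" for x in sorted(thresholds)]
    labels = [f"<{t[0]}"]
    labels += [f"{a}-{b}" for a, b in zip(t[:-1], t[1:])]
    labels.append(f">{t[-1]}")
    return tuple(labels)


def pseudo_contour(
    exceedance: dict[float, np.ndarray],
    geometry: GridGeometry,
    cutoffs: dict[float, float] | None = None,
) -> BandMap:
    """Combine per-threshold exceedance maps into a band map.

    Each valid cell is assigned the band immediately above the *highest*
    threshold whose exceedance map is 1 there; a cell exceeding nothing
    falls in the lowest band.  Cells whose exceedance pattern is not nested
    (exceeds a high threshold but not some lower one) are flagged in the
    inconsistency mask and still resolved by the highest-exceeded rule.
    """
    thresholds = tuple(sorted(exceedance))
    grids = [np.asarray(exceedance[t], dtype=float) for t in thresholds]
    shape = geometry.shape
    for t, g in zip(thresholds, grids):
        if g.shape != shape:
            raise GeometryError(f"exceedance grid at {t} has shape {g.shape} != {shape}")
    stackarr = np.stack(grids)  # (k, nrows, ncols)
    nodata = np.isnan(stackarr).any(axis=0)
    binary = np.nan_to_num(stackarr, nan=0.0).astype(int)
    # highest exceeded threshold index + 1; 0 when nothing is exceeded
    k = len(thresholds)
    idx = np.arange(1, k + 1)[:, None, None]
    bands = np.max(binary * idx, axis=0)
    # nesting violation: some threshold below the highest-exceeded is 0
    below_highest = idx < np.maximum(bands, 1)[None, ...]
    inconsistent = ((binary == 0) & below_highest).any(axis=0) & ~nodata
    bands = bands.astype(np.int32)
    bands[nodata] = -1
    return BandMap(
        bands=bands,
        labels=band_labels(thresholds),
        thresholds=thresholds,
        cutoffs=dict(cutoffs or {}),
        inconsistency_mask=inconsistent,
        geometry=geometry,
    )
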