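"""File formats: well CSVs, ESRI ASCII grids and JSON sidecars.

Grids travel as single-band ESRI ASCII rasters (plain text, readable by any
GIS) with geometry in the header; a predictor stack is a directory of
``.asc`` files plus a JSON legend mapping layer name → kind.  Well tables
are CSVs with columns ``id, x, y, as_ugL`` (extra columns pass through).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import GeometryError, GridGeometry
from .synthetic import PredictorStack

WELL_COLUMNS = ("id", "x", "y", "as_ugL")
NODATA = -9999.0


class SchemaError(ValueError):
    """An input file does not match its required schema."""


def read_wells(path) -> pd.DataFrame:
    """Read a well table CSV, reporting malformed rows with line numbers."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=list(WELL_COLUMNS))
    missing = [c for c in WELL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    bad_lines = []
    for col in ("x", "y", "as_ugL"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        # +2: one for the header, one for 1-based numbering
        bad_lines += [(int(i) + 2, col, df.loc[i, col]) for i in bad]
        df[col] = coerced
    if bad_lines:
        detail = "; ".join(f"line {ln}: {col}={val!r}" for ln, col, val in bad_lines)
        raise SchemaError(f"{path}: non-numeric values ({detail})")
    return df


def write_wells(table: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def write_asc(grid: np.ndarray, geometry: GridGeometry, path, nodata: float = NODATA) -> None:
    """Write one grid as an ESRI ASCII raster (row 0 is southernmost)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.asarray(grid, dtype=float).copy()
    data[np.isnan(data)] = nodata
    header = (
        f"ncols {geometry.ncols}\n"
        f"nrows {geometry.nrows}\n"
        f"xllcorner {geometry.x_origin!r}\n"
        f"yllcorner {geometry.y_origin!r}\n"
        f"cellsize {geometry.cell_size!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        # ESRI ASCII stores the top row first
        np.savetxt(fh, data[::-1], fmt="%.10g")


def read_asc(path) -> tuple[np.ndarray, GridGeometry]:
    """Read an ESRI ASCII raster; nodata cells become NaN."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    geom = GridGeometry(
        header["xllcorner"],
        header["yllcorner"],
        header["cellsize"],
        int(header["nrows"]),
        int(header["ncols"]),
    )
    data = np.atleast_2d(data)[::-1].copy()
    data[data == header.get("nodata_value", NODATA)] = np.nan
    return data, geom


def write_stack(stack: PredictorStack, directory) -> None:
    """Write a stack as one .asc per layer plus a JSON legend."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, grid in stack.layers.items():
        out = grid.copy()
        out[stack.nodata_mask] = np.nan
        write_asc(out, stack.geometry, directory / f"{name}.asc")
    legend = {"layer_kind": stack.layer_kind}
    (directory / "legend.json").write_text(json.dumps(legend, indent=2))


def read_stack(directory) -> PredictorStack:
    """Read a stack directory written by :func:`write_stack`.

    All layers must share one geometry; the legend must name every layer.
    """
    directory = Path(directory)
    legend_path = directory / "legend.json"
    if not legend_path.exists():
        raise SchemaError(f"missing legend: {legend_path}")
    kinds = json.loads(legend_path.read_text())["layer_kind"]
    layers: dict[str, np.ndarray] = {}
    geom: GridGeometry | None = None
    mask = None
    for asc in sorted(directory.glob("*.asc")):
        name = asc.stem
        if name not in kinds:
            raise SchemaError(f"legend does not describe layer {name!r}")
        grid, g = read_asc(asc)
        if geom is None:
            geom = g
            mask = np.isnan(grid)
        elif g != geom:
            raise GeometryError(f"layer {name!r} geometry {g} != {geom}")
        else:
            mask |= np.isnan(grid)
        layers[name] = grid
    if geom is None:
        raise SchemaError(f"no .asc layers in {directory}")
    missing = set(kinds) - set(layers)
    if missing:
        raise SchemaError(f"legend names absent layers: {sorted(missing)}")
    for name in layers:
        layers[name] = np.nan_to_num(layers[name], nan=0.0)
    return PredictorStack(layers, dict(kinds), geom, mask)


def write_model_json(final, norm_stats, cutoff, path) -> None:
    """Persist a final model: combination, coefficients, stats, cutoff."""
    payload = {
        "threshold": final.threshold,
        "variables": list(final.variables),
        "intercept": final.intercept,
        "coefficients": [float(c) for c in final.coefficients],
        "intercept_sd": final.intercept_sd,
        "coefficient_sd": [float(s) for s in final.coef_sd],
        "mean_test_auc": final.mean_test_auc,
        "whole_data_auc": final.whole_data_auc,
        "count": final.count,
        "cutoff": cutoff,
        "normalization": norm_stats.to_dict(),
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=2))
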