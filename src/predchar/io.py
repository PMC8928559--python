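"""Reading and writing occurrence tables, evaluation tables, and rasters.

Tabular formats are plain delimited text (comma by default, "." decimal).
Rasters are ESRI ASCII grids (text) or GeoTIFF via :mod:`tifffile`; the grid
spec of a GeoTIFF is carried as JSON in the ImageDescription tag so that a
write/read round trip is lossless without external geo libraries.
"""

from __future__ import annotations

import json
import os
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    EVALUATION_COLUMNS,
    EnvironmentalStack,
    DimensionError,
    GridSpec,
    SchemaError,
    ValidationError,
    VariableRegistry,
    genebank_held,
)

REQUIRED_OCCURRENCE_COLUMNS = ("pop_id", "taxon", "lon", "lat")


def read_occurrences(
    path: str | os.PathLike,
    registry: VariableRegistry | None = None,
    sep: str = ",",
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read an occurrence table (population per row) from delimited text.

    Parameters
    ----------
    path
        Delimited text file with a header row. Required columns: pop_id,
        taxon, lon, lat. Optional: country, source, elc_category, and any
        environmental-variable columns declared in ``registry``.
    registry
        If given, environmental columns are restricted to registered names;
        unknown numeric columns are kept but not treated as environment.
    sep
        Field separator; pass ";" for semicolon exports.
    column_map
        Optional mapping from the file's column headers to canonical names,
        for supplementary exports whose headers differ.

    Returns
    -------
    DataFrame with canonical columns, a derived boolean ``genebank_held``,
    NaN for unparseable numeric cells (never silently 0), and
    ``df.attrs["env_columns"]`` listing the environmental columns found.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in REQUIRED_OCCURRENCE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    dup = df["pop_id"][df["pop_id"].duplicated()].unique().tolist()
    if dup:
        raise ValidationError(f"duplicate pop_id values: {dup}")

    numeric_cols = [c for c in df.columns if c not in ("pop_id", "taxon", "country", "source")]
    for col in numeric_cols:
        df[col] = pd.to_numeric(df[col], errors="coerce")
        df.loc[df[col] == -9999, col] = np.nan

    bad_lon = df["lon"].notna() & ~df["lon"].between(-180, 180)
    bad_lat = df["lat"].notna() & ~df["lat"].between(-90, 90)
    if bad_lon.any() or bad_lat.any():
        bad = df.loc[bad_lon | bad_lat, "pop_id"].tolist()
        raise ValidationError(f"coordinates out of range for: {bad}")

    df["genebank_held"] = df["pop_id"].map(genebank_held)
    if "elc_category" in df.columns:
        df["elc_category"] = df["elc_category"].astype("Int64")

    env_cols = [
        c
        for c in df.columns
        if c not in ("pop_id", "taxon", "lon", "lat", "country", "source", "genebank_held", "elc_category")
    ]
    if registry is not None:
        unknown = [c for c in env_cols if c not in registry]
        env_cols = [c for c in env_cols if c in registry]
        df.attrs["unregistered_columns"] = unknown
    df.attrs["env_columns"] = env_cols
    return df


def write_occurrences(df: pd.DataFrame, path: str | os.PathLike, sep: str = ",") -> None:
    df.to_csv(path, sep=sep, index=False)


def read_evaluations(
    path: str | os.PathLike,
    sep: str = ",",
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a trait-evaluation table: accession_id, lon, lat, trait, dsr."""
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in EVALUATION_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    for col in ("lon", "lat", "dsr"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df["dsr"].notna() & ~df["dsr"].between(0, 100)
    if bad.any():
        raise ValidationError(
            f"dsr outside [0, 100] for: {df.loc[bad, 'accession_id'].tolist()}"
        )
    return df


# ---------------------------------------------------------------------------
# Rasters

_ASC_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


def write_raster(grid: np.ndarray, spec: GridSpec, path: str | os.PathLike) -> None:
    """Write a single-layer raster; dialect chosen by extension (.asc / .tif)."""
    path = os.fspath(path)
    grid = np.asarray(grid)
    if grid.shape != (spec.n_rows, spec.n_cols):
        raise DimensionError(f"grid shape {grid.shape} does not match spec")
    if path.endswith((".tif", ".tiff")):
        _write_geotiff(grid, spec, path)
    else:
        _write_ascii(grid, spec, path)


def read_raster(path: str | os.PathLike) -> tuple[np.ndarray, GridSpec]:
    """Read a raster; no-data cells come back as NaN (float grids only)."""
    path = os.fspath(path)
    if path.endswith((".tif", ".tiff")):
        return _read_geotiff(path)
    return _read_ascii(path)


def _write_ascii(grid: np.ndarray, spec: GridSpec, path: str) -> None:
    out = np.array(grid, dtype=float, copy=True)
    out[~np.isfinite(out)] = spec.nodata
    is_int = np.issubdtype(grid.dtype, np.integer)
    with open(path, "w") as fh:
        fh.write(f"ncols {spec.n_cols}\n")
        fh.write(f"nrows {spec.n_rows}\n")
        fh.write(f"xllcorner {spec.xll!r}\n")
        fh.write(f"yllcorner {spec.yll!r}\n")
        fh.write(f"cellsize {spec.cell_size!r}\n")
        fh.write(f"NODATA_value {spec.nodata!r}\n")
        fmt = "%d" if is_int else "%.10g"
        np.savetxt(fh, out, fmt=fmt)


def _read_ascii(path: str) -> tuple[np.ndarray, GridSpec]:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        data = np.loadtxt(fh, ndmin=2)
    spec = GridSpec(
        n_rows=int(header["nrows"]),
        n_cols=int(header["ncols"]),
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cell_size=header["cellsize"],
        nodata=header.get("nodata_value", -9999.0),
    )
    data[data == spec.nodata] = np.nan
    return data, spec


def _write_geotiff(grid: np.ndarray, spec: GridSpec, path: str) -> None:
    import tifffile

    meta = {
        "n_rows": spec.n_rows,
        "n_cols": spec.n_cols,
        "xll": spec.xll,
        "yll": spec.yll,
        "cell_size": spec.cell_size,
        "nodata": spec.nodata,
    }
    out = np.array(grid, dtype=float, copy=True)
    out[~np.isfinite(out)] = spec.nodata
    tifffile.imwrite(path, out, description=json.dumps(meta))


def _read_geotiff(path: str) -> tuple[np.ndarray, GridSpec]:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray().astype(float)
        desc = page.tags.get("ImageDescription")
        meta = json.loads(desc.value) if desc is not None else {}
    spec = GridSpec(
        n_rows=int(meta.get("n_rows", data.shape[0])),
        n_cols=int(meta.get("n_cols", data.shape[1])),
        xll=float(meta.get("xll", 0.0)),
        yll=float(meta.get("yll", 0.0)),
        cell_size=float(meta.get("cell_size", 2.5 / 60.0)),
        nodata=float(meta.get("nodata", -9999.0)),
    )
    data[data == spec.nodata] = np.nan
    return data, spec


def read_stack(
    directory: str | os.PathLike, components: Mapping[str, str]
) -> EnvironmentalStack:
    """Assemble a stack from per-layer rasters named ``<variable>.asc``/``.tif``.

    ``components`` maps variable name -> component tag.  All layers must share
    one grid spec; a mismatch raises :class:`DimensionError`.
    """
    directory = os.fspath(directory)
    stack: EnvironmentalStack | None = None
    for name, comp in components.items():
        for ext in (".asc", ".tif", ".tiff"):
            candidate = os.path.join(directory, name + ext)
            if os.path.exists(candidate):
                break
        else:
            raise FileNotFoundError(f"no raster found for layer {name!r} in {directory}")
        data, spec = read_raster(candidate)
        if stack is None:
            stack = EnvironmentalStack(grid=spec)
        elif (
            spec.n_rows != stack.grid.n_rows
            or spec.n_cols != stack.grid.n_cols
            or not np.isclose(spec.cell_size, stack.grid.cell_size)
        ):
            raise DimensionError(f"layer {name!r} grid spec differs from the stack's")
        stack.add_layer(name, data, comp)
    if stack is None:
        raise ValueError("components mapping is empty")
    return stack


def write_stack(stack: EnvironmentalStack, directory: str | os.PathLike, fmt: str = "asc") -> None:
    os.makedirs(directory, exist_ok=True)
    for name, arr in stack.layers.items():
        write_raster(arr, stack.grid, os.path.join(os.fspath(directory), f"{name}.{fmt}"))
    manifest = {name: stack.component[name] for name in stack.layers}
    with open(os.path.join(os.fspath(directory), "components.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)


# ---------------------------------------------------------------------------
# Point extraction


def extract_at_points(
    stack: EnvironmentalStack,
    lon: Sequence[float] | np.ndarray,
    lat: Sequence[float] | np.ndarray,
    layers: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Nearest-cell-center extraction of layer values at points.

    Points outside the grid extent, or landing on no-data cells, yield NaN
    and are flagged (``out_of_extent`` / ``on_nodata``) rather than raising.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    names = list(layers) if layers is not None else stack.names()
    n = len(lon)
    spec = stack.grid

    rows = np.full(n, -1, dtype=int)
    cols = np.full(n, -1, dtype=int)
    out_of_extent = np.zeros(n, dtype=bool)
    for i in range(n):
        idx = spec.index_of(lon[i], lat[i]) if np.isfinite(lon[i]) and np.isfinite(lat[i]) else None
        if idx is None:
            out_of_extent[i] = True
        else:
            rows[i], cols[i] = idx

    result = pd.DataFrame(index=range(n))
    inside = ~out_of_extent
    for name in names:
        arr = stack.layers[name]
        vals = np.full(n, np.nan)
        vals[inside] = arr[rows[inside], cols[inside]]
        result[name] = vals
    on_nodata = inside & result[names].isna().any(axis=1).to_numpy()
    result["out_of_extent"] = out_of_extent
    result["on_nodata"] = on_nodata
    return result
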