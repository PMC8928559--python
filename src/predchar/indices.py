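"""Aridity indices and the site-classification rule tables.

The De Martonne aridity index summarizes water availability as precipitation
over temperature-plus-ten:

    annual:   I = P / (T + 10)          P in mm/yr, T in deg C
    monthly:  I_m = 12 * P_m / (T_m + 10)
    flowering: mean of the monthly indices for March-June

Lower values are more arid.  The +10 offset keeps the denominator positive
over the temperatures where the index is used; below -10 deg C the index is
undefined and this module raises rather than clamping.

Three rule tables classify sites: a six-class aridity scheme, a five-way
topsoil texture scheme (Clay / Silty Clay / Sandy Clay / Silty Clay Loam /
Other, from clay-silt-sand percentages), and a five-class soil-salinity
scheme from saturation-extract conductivity in dS/m.  All interval bins are
left-closed, right-open.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import DomainError, ValidationError

FLOWERING_MONTHS = (3, 4, 5, 6)

ARIDITY_CLASSES = (
    "deserts/extremely arid",
    "semi-desert/arid",
    "semi-arid",
    "sub-humid",
    "humid",
    "per-humid",
)
_ARIDITY_EDGES = (5.0, 10.0, 20.0, 30.0, 60.0)

TEXTURE_CLASSES = ("Clay", "Silty Clay", "Sandy Clay", "Silty Clay Loam", "Other")
#: Waterlogging-prone (poorly draining) texture classes.
POOR_DRAINAGE_TEXTURES = frozenset(TEXTURE_CLASSES[:4])

SALINITY_CLASSES = (
    "non-saline",
    "slightly saline",
    "moderately saline",
    "strongly saline",
    "very strongly saline",
)
_SALINITY_EDGES = (2.0, 4.0, 8.0, 16.0)

#: Tolerance on clay+silt+sand (%), absorbing rounding in soil databases.
COMPOSITION_TOLERANCE = 2.0


def demartonne_annual(P, T):
    """Annual De Martonne aridity index P/(T+10).

    Parameters are annual precipitation (mm) and annual mean temperature
    (deg C); scalars or arrays.  Raises :class:`DomainError` for T <= -10
    or negative precipitation.
    """
    P = np.asarray(P, dtype=float)
    T = np.asarray(T, dtype=float)
    if np.any(T <= -10):
        raise DomainError("De Martonne index undefined for T <= -10 degC")
    if np.any(P < 0):
        raise DomainError("precipitation must be non-negative")
    out = P / (T + 10.0)
    return float(out) if out.ndim == 0 else out


def demartonne_monthly(Pm, Tm):
    """Monthly De Martonne index 12*Pm/(Tm+10) (Pm = monthly precipitation, mm)."""
    Pm = np.asarray(Pm, dtype=float)
    Tm = np.asarray(Tm, dtype=float)
    if np.any(Tm <= -10):
        raise DomainError("De Martonne index undefined for Tm <= -10 degC")
    if np.any(Pm < 0):
        raise DomainError("precipitation must be non-negative")
    out = 12.0 * Pm / (Tm + 10.0)
    return float(out) if out.ndim == 0 else out


def demartonne_flowering(Pm, Tm, months=FLOWERING_MONTHS):
    """Flowering-season index: mean monthly index over March-June.

    ``Pm``/``Tm`` are length-12 sequences (January first) or mappings keyed
    by month number; only the flowering months are used.
    """

    def pick(seq, month):
        if hasattr(seq, "keys"):
            return seq[month]
        return seq[month - 1]

    monthly = [demartonne_monthly(pick(Pm, m), pick(Tm, m)) for m in months]
    return float(np.mean(monthly, axis=0)) if np.ndim(monthly[0]) == 0 else np.mean(monthly, axis=0)


def classify_aridity(index):
    """Six-class aridity label for a De Martonne index value (vectorized)."""
    arr = np.asarray(index, dtype=float)
    if np.any(arr < 0):
        raise DomainError("aridity index must be non-negative")
    codes = np.searchsorted(_ARIDITY_EDGES, arr, side="right")
    out = np.take(ARIDITY_CLASSES, codes)
    return str(out) if out.ndim == 0 else out


def classify_texture(clay: float, silt: float, sand: float) -> str:
    """Topsoil texture from clay/silt/sand percentages.

    Rules are evaluated in fixed order, first match winning:

    1. Clay:            clay >= 40, sand <= 45, silt < 40
    2. Silty Clay:      clay >= 40, silt >= 40
    3. Sandy Clay:      clay >= 35, sand > 45
    4. Silty Clay Loam: 27 <= clay < 40, sand <= 20
    5. Other
    """
    total = clay + silt + sand
    if not (100.0 - COMPOSITION_TOLERANCE <= total <= 100.0 + COMPOSITION_TOLERANCE):
        raise ValidationError(f"clay+silt+sand = {total:g}, outside 100 +/- {COMPOSITION_TOLERANCE:g}")
    if min(clay, silt, sand) < 0:
        raise ValidationError("negative composition fraction")
    if clay >= 40 and sand <= 45 and silt < 40:
        return "Clay"
    if clay >= 40 and silt >= 40:
        return "Silty Clay"
    if clay >= 35 and sand > 45:
        return "Sandy Clay"
    if 27 <= clay < 40 and sand <= 20:
        return "Silty Clay Loam"
    return "Other"


def classify_salinity(ec):
    """Salinity class from topsoil conductivity (dS/m), left-closed bins at 2/4/8/16."""
    arr = np.asarray(ec, dtype=float)
    if np.any(arr < 0):
        raise DomainError("conductivity must be non-negative")
    codes = np.searchsorted(_SALINITY_EDGES, arr, side="right")
    out = np.take(SALINITY_CLASSES, codes)
    return str(out) if out.ndim == 0 else out


def annotate_indices(
    df: pd.DataFrame,
    precip_col: str = "annual_precip",
    temp_col: str = "annual_mean_temp",
    monthly_precip_cols: list[str] | None = None,
    monthly_temp_cols: list[str] | None = None,
    clay_col: str = "topsoil_clay",
    silt_col: str = "topsoil_silt",
    sand_col: str = "topsoil_sand",
    ec_col: str = "topsoil_ec",
) -> pd.DataFrame:
    """Append index and classification columns to a population table.

    Adds ``iar_dm``, ``iar_dm_f`` (when monthly columns are present),
    ``aridity_class``, ``aridity_class_f``, ``texture_class`` and
    ``salinity_class``; rows with missing inputs get NaN/None, never a
    fabricated class.  Returns a new DataFrame.
    """
    out = df.copy()

    if precip_col in out.columns and temp_col in out.columns:
        ok = out[precip_col].notna() & out[temp_col].notna()
        iar = np.full(len(out), np.nan)
        iar[ok.to_numpy()] = demartonne_annual(
            out.loc[ok, precip_col].to_numpy(), out.loc[ok, temp_col].to_numpy()
        )
        out["iar_dm"] = iar
        out["aridity_class"] = [classify_aridity(v) if np.isfinite(v) else None for v in iar]

    if monthly_precip_cols and monthly_temp_cols:
        pm = out[monthly_precip_cols].to_numpy(dtype=float)
        tm = out[monthly_temp_cols].to_numpy(dtype=float)
        ok = np.isfinite(pm).all(axis=1) & np.isfinite(tm).all(axis=1)
        iarf = np.full(len(out), np.nan)
        if ok.any():
            flower = [demartonne_monthly(pm[ok, m - 1], tm[ok, m - 1]) for m in FLOWERING_MONTHS]
            iarf[ok] = np.mean(flower, axis=0)
        out["iar_dm_f"] = iarf
        out["aridity_class_f"] = [classify_aridity(v) if np.isfinite(v) else None for v in iarf]

    if all(c in out.columns for c in (clay_col, silt_col, sand_col)):
        textures = []
        for clay, silt, sand in out[[clay_col, silt_col, sand_col]].to_numpy(dtype=float):
            if np.isfinite([clay, silt, sand]).all():
                textures.append(classify_texture(clay, silt, sand))
            else:
                textures.append(None)
        out["texture_class"] = textures

    if ec_col in out.columns:
        out["salinity_class"] = [
            classify_salinity(v) if np.isfinite(v) else None
            for v in out[ec_col].to_numpy(dtype=float)
        ]
    return out
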