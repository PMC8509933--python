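"""Residual diagnostics for scaling fits.

Residuals on the log scale (observed minus fitted ln pills) carry the
diagnostic weight of the scaling analysis: standardized against the fit's
residual SD they drive outlier flagging, a loess smoother of standardized
residuals against log-population reveals non-linearity (the "U" shape
that motivates the spline), and a GeoJSON export makes per-unit residuals
joinable to unit geographies for mapping.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .scaling import FitError, PiecewiseFit, fit_piecewise, percentile_of, search_knot

RESIDUAL_COLUMNS = ["unit_id", "population", "residual", "std_residual", "outlier"]


def compute_residuals(frame: pd.DataFrame, fit) -> pd.DataFrame:
    """Per-unit residuals (observed minus fitted on the log scale).

    ``std_residual`` divides by the fit's df-corrected residual SD.  The
    frame must be the one the fit was produced on (checked by unit set).
    """
    if fit.unit_ids and set(fit.unit_ids) != set(frame["unit_id"]):
        raise FitError("residuals requested on a different unit set than the fit")
    if fit.fitted is None or len(fit.fitted) != len(frame):
        raise FitError("fit does not carry fitted values for this data")
    resid = frame["y"].to_numpy(dtype=float) - np.asarray(fit.fitted, dtype=float)
    std = resid / fit.sigma if fit.sigma > 0 else np.zeros_like(resid)
    return pd.DataFrame({
        "unit_id": frame["unit_id"].to_numpy(),
        "population": np.exp(frame["x"].to_numpy(dtype=float)),
        "residual": resid,
        "std_residual": std,
        "outlier": np.zeros(len(resid), dtype=bool),
    })


def flag_outliers(records: pd.DataFrame, threshold: float = 3.0) -> pd.DataFrame:
    """Flag |standardized residual| >= threshold; sign kept in ``outlier_sign``."""
    out = records.copy()
    std = out["std_residual"].to_numpy(dtype=float)
    out["outlier"] = np.abs(std) >= threshold
    out["outlier_sign"] = np.sign(std).astype(int) * out["outlier"].astype(int)
    return out


@dataclass(frozen=True)
class ExclusionRefit:
    """Result of refitting after dropping units (outlier sensitivity check)."""
    fit: PiecewiseFit
    knot: float
    knot_percentile: float        # percentile of the knot in the remaining sample
    mode: str                     # "fixed" or "search"
    excluded: tuple


def rerun_excluding(frame: pd.DataFrame, exclusion, knot: float,
                    knot_mode: str = "fixed", covariates=None) -> ExclusionRefit:
    """Refit the spline model after excluding units.

    ``knot_mode="fixed"`` keeps the supplied knot; ``"search"`` re-runs
    the knot search on the reduced sample and reports the new knot and its
    population percentile.
    """
    exclusion = set(exclusion)
    kept = frame[~frame["unit_id"].isin(exclusion)]
    if knot_mode == "fixed":
        fit = fit_piecewise(kept, knot, covariates=covariates)
        new_knot = float(knot)
    elif knot_mode == "search":
        result = search_knot(kept, covariates=covariates)
        fit, new_knot = result.fit, result.knot
    else:
        raise FitError(f"unknown knot_mode {knot_mode!r}")
    pops = np.exp(kept["x"].to_numpy(dtype=float))
    return ExclusionRefit(fit=fit, knot=new_knot,
                          knot_percentile=percentile_of(new_knot, pops),
                          mode=knot_mode, excluded=tuple(sorted(exclusion)))


@dataclass(frozen=True)
class SmootherCurve:
    grid: np.ndarray = field(compare=False)     # ln-population points
    values: np.ndarray = field(compare=False)   # smoothed standardized residual
    span: float = 0.75


def smooth_std_residuals(records: pd.DataFrame, span: float = 0.75,
                         grid_size: int = 101) -> SmootherCurve:
    """Loess smoother of standardized residuals on ln(population).

    Evaluated on an even grid spanning the observed ln-population range.
    """
    if not (0.0 < span <= 1.0):
        raise FitError(f"span must be in (0, 1], got {span}")
    if len(records) < 10:
        raise FitError(f"need at least 10 records for a smoother, got {len(records)}")
    x = np.log(records["population"].to_numpy(dtype=float))
    z = records["std_residual"].to_numpy(dtype=float)
    grid = np.linspace(x.min(), x.max(), max(int(grid_size), 100))
    smoothed = lowess(z, x, frac=span, xvals=grid)
    return SmootherCurve(grid=grid, values=np.asarray(smoothed, dtype=float),
                         span=span)


def export_residual_geo(records: pd.DataFrame, geometry_table: dict,
                        path) -> list:
    """Write residuals as a GeoJSON FeatureCollection joinable to geography.

    ``geometry_table`` maps unit_id to a GeoJSON-like geometry mapping or
    a shapely geometry.  Units without geometry are skipped (returned as a
    report list) but the file is still written; a malformed geometry is a
    hard error naming the unit.
    """
    import shapely.geometry

    features, skipped = [], []
    for _, row in records.iterrows():
        uid = row["unit_id"]
        if uid not in geometry_table:
            skipped.append(uid)
            continue
        geom = geometry_table[uid]
        try:
            shp = (geom if isinstance(geom, shapely.geometry.base.BaseGeometry)
                   else shapely.geometry.shape(geom))
            if not shp.is_valid:
                raise ValueError("invalid geometry")
            geo_mapping = shapely.geometry.mapping(shp)
        except Exception as exc:
            raise FitError(f"malformed geometry for unit {uid}: {exc}") from exc
        features.append({
            "type": "Feature",
            "geometry": geo_mapping,
            "properties": {
                "unit_id": str(uid),
                "population": float(row["population"]),
                "residual": float(row["residual"]),
                "std_residual": float(row["std_residual"]),
                "outlier": bool(row["outlier"]),
            },
        })
    collection = {"type": "FeatureCollection", "features": features}
    with open(path, "w") as fh:
        json.dump(collection, fh)
    return skipped
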