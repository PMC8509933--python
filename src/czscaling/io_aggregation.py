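"""County-to-unit aggregation of pill counts and populations.

Counties are the finest spatial resolution of the input data: annual
oxycodone/hydrocodone pill counts and annual census population estimates,
keyed by 5-digit FIPS code.  The analysis units are commuting zones (CZs)
or core-based statistical areas (CBSAs), defined by a county->unit
crosswalk.  This module validates the county tables, sums pills and
averages populations over the study window, drops units touching excluded
states (by default the non-contiguous AK and HI), and attaches census
regions by a population-majority rule.
"""
from __future__ import annotations

import json
import logging
import re

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

FIPS_RE = re.compile(r"^[0-9]{5}$")

DEFAULT_WINDOW = (2006, 2014)
DEFAULT_EXCLUDED_STATES = frozenset({"AK", "HI"})

#: US Census Bureau regions for the 48 contiguous states + DC (+ AK/HI for
#: completeness; excluded-state units are normally dropped before regions
#: are assigned).
CENSUS_REGIONS = {
    "CT": "Northeast", "ME": "Northeast", "MA": "Northeast", "NH": "Northeast",
    "RI": "Northeast", "VT": "Northeast", "NJ": "Northeast", "NY": "Northeast",
    "PA": "Northeast",
    "IL": "Midwest", "IN": "Midwest", "MI": "Midwest", "OH": "Midwest",
    "WI": "Midwest", "IA": "Midwest", "KS": "Midwest", "MN": "Midwest",
    "MO": "Midwest", "NE": "Midwest", "ND": "Midwest", "SD": "Midwest",
    "DE": "South", "FL": "South", "GA": "South", "MD": "South", "NC": "South",
    "SC": "South", "VA": "South", "DC": "South", "WV": "South", "AL": "South",
    "KY": "South", "MS": "South", "TN": "South", "AR": "South", "LA": "South",
    "OK": "South", "TX": "South",
    "AZ": "West", "CO": "West", "ID": "West", "MT": "West", "NV": "West",
    "NM": "West", "UT": "West", "WY": "West", "CA": "West", "OR": "West",
    "WA": "West", "AK": "West", "HI": "West",
}

UNIT_COLUMNS = ["unit_id", "pills_total", "pop_mean", "region", "stratum",
                "n_counties"]

_KIND_STRATUM = {"CZ": "", "CBSA_METRO": "metro", "CBSA_MICRO": "micro"}


class AggregationError(ValueError):
    """Raised when input tables violate the aggregation contract."""


def _check_fips(series: pd.Series, table: str) -> None:
    bad = series[~series.astype(str).str.match(FIPS_RE)]
    if len(bad):
        raise AggregationError(
            f"{table}: county_fips must be 5 digits; offenders: "
            f"{sorted(bad.astype(str).unique())[:10]}")


def aggregate_to_units(pills: pd.DataFrame,
                       pops: pd.DataFrame,
                       xwalk: pd.DataFrame,
                       excluded_states: frozenset = DEFAULT_EXCLUDED_STATES,
                       window: tuple[int, int] = DEFAULT_WINDOW) -> pd.DataFrame:
    """Aggregate county pills and populations to spatial units.

    Parameters
    ----------
    pills : DataFrame with columns county_fips, year, pills.
    pops : DataFrame with columns county_fips, year, population.
        Every county in the crosswalk must have a population for every
        year of the window; missing years are a hard error, never imputed.
    xwalk : DataFrame with columns county_fips, unit_id, unit_kind, state.
    excluded_states : any unit containing at least one county in one of
        these states is dropped entirely (default: AK and HI, the
        non-contiguous states).
    window : inclusive (first_year, last_year) study window.

    Returns
    -------
    DataFrame with one row per retained unit, sorted by unit_id, columns
    ``unit_id, pills_total, pop_mean, region, stratum, n_counties`` plus a
    ``state_pops`` object column (state -> mean population contribution)
    used later for region assignment.  ``pills_total`` is the sum of pills
    over all member counties and window years; ``pop_mean`` is the mean
    over window years of the unit's annual population total.
    """
    lo, hi = int(window[0]), int(window[1])
    if hi < lo:
        raise AggregationError(f"empty study window {window}")
    years = list(range(lo, hi + 1))

    pills = pills.copy()
    pops = pops.copy()
    xwalk = xwalk.copy()
    for df, name in ((pills, "pills"), (pops, "population"), (xwalk, "crosswalk")):
        df["county_fips"] = df["county_fips"].astype(str)
        _check_fips(df["county_fips"], name)

    if (pills["pills"] < 0).any():
        bad = pills.loc[pills["pills"] < 0, "county_fips"].tolist()
        raise AggregationError(f"negative pill counts for counties {bad}")
    if (pops["population"] <= 0).any():
        bad = pops.loc[pops["population"] <= 0, "county_fips"].tolist()
        raise AggregationError(f"non-positive populations for counties {bad}")
    dup = xwalk.duplicated(subset=["county_fips", "unit_kind"])
    if dup.any():
        raise AggregationError(
            "crosswalk maps a county to multiple units of the same kind: "
            f"{sorted(xwalk.loc[dup, 'county_fips'].unique())}")

    missing = set(pills["county_fips"]) - set(xwalk["county_fips"])
    if missing:
        raise AggregationError(
            f"counties with pills but no crosswalk entry: {sorted(missing)}")

    pw = pills[pills["year"].between(lo, hi)]
    pop_w = pops[pops["year"].between(lo, hi)]

    # every crosswalk county needs every window year of population
    have = pop_w.groupby("county_fips")["year"].nunique()
    need = xwalk["county_fips"].unique()
    short = [c for c in need if have.get(c, 0) < len(years)]
    if short:
        raise AggregationError(
            f"counties missing population in some window year: {sorted(short)[:10]}")

    county_pills = pw.groupby("county_fips")["pills"].sum()
    merged = xwalk.merge(pop_w, on="county_fips", how="left")

    rows = []
    for unit_id, grp in merged.groupby("unit_id", sort=True):
        counties = grp["county_fips"].unique()
        states = set(grp["state"])
        if states & set(excluded_states):
            log.warning("dropping unit %s: touches excluded state(s) %s",
                        unit_id, sorted(states & set(excluded_states)))
            continue
        annual = grp.groupby("year")["population"].sum()
        pop_mean = float(annual.mean())
        state_pops = {s: float(g.groupby("year")["population"].sum().mean())
                      for s, g in grp.groupby("state")}
        total = int(sum(county_pills.get(c, 0) for c in counties))
        kinds = grp["unit_kind"].unique()
        stratum = _KIND_STRATUM.get(kinds[0], str(kinds[0])) if len(kinds) == 1 else ""
        rows.append({"unit_id": unit_id, "pills_total": total,
                     "pop_mean": pop_mean, "region": "", "stratum": stratum,
                     "n_counties": len(counties), "state_pops": state_pops})
    units = pd.DataFrame(rows, columns=UNIT_COLUMNS + ["state_pops"])
    return units.reset_index(drop=True)


def assign_region(units: pd.DataFrame,
                  state_region_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Attach a census region to every unit.

    A unit spanning several states takes the region of the state that
    contributes the largest mean population; a tie goes to the
    alphabetically first region among the tied states (with a warning).
    Requires the ``state_pops`` column written by :func:`aggregate_to_units`.
    """
    if state_region_map is None:
        state_region_map = CENSUS_REGIONS
    if "state_pops" not in units.columns:
        raise AggregationError("units table lacks state_pops; run aggregate_to_units first")

    regions = []
    for _, row in units.iterrows():
        state_pops = row["state_pops"]
        unmapped = [s for s in state_pops if s not in state_region_map]
        if unmapped:
            raise AggregationError(
                f"unit {row['unit_id']}: states {unmapped} missing from region map")
        best = max(state_pops.values())
        winners = sorted(state_region_map[s] for s, p in state_pops.items() if p == best)
        if len(winners) > 1:
            log.warning("unit %s: population tie across states; taking region %s",
                        row["unit_id"], winners[0])
        regions.append(winners[0])
    out = units.copy()
    out["region"] = regions
    return out


def write_units_csv(units: pd.DataFrame, path) -> None:
    """Write a unit table to CSV (dict-valued columns serialized as JSON)."""
    out = units.copy()
    for col in out.columns:
        if out[col].map(lambda v: isinstance(v, dict)).any():
            out[col] = out[col].map(json.dumps)
    out.to_csv(path, index=False)


def read_units_csv(path) -> pd.DataFrame:
    """Read a unit table CSV, validating schema and numeric columns.

    Unknown extra columns are preserved verbatim.  Numeric validation
    errors name the offending data row (1-based, excluding the header).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["unit_id", "pills_total", "pop_mean", "region", "stratum"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise AggregationError(f"units CSV {path}: missing columns {missing}")

    for col, caster in (("pills_total", int), ("pop_mean", float)):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise AggregationError(
                f"units CSV {path}: non-numeric {col} at data row {row}")
        if (parsed < 0).any():
            row = int((parsed < 0).idxmax()) + 1
            raise AggregationError(
                f"units CSV {path}: negative {col} at data row {row}")
        df[col] = parsed.astype(caster)
    if "n_counties" in df.columns:
        df["n_counties"] = pd.to_numeric(df["n_counties"]).astype(int)
    return df
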