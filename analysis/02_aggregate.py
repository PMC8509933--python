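#!/usr/bin/env python
"""Aggregate the simulated county tables to units and attach regions.

Reads the CSVs written by 01_simulate.py, runs the same aggregation used
for real county data (sum pills over the window, average annual
populations, drop excluded-state units, region by population majority),
verifies pill-count conservation against the simulated truth, and writes
results/units.csv.
"""
from pathlib import Path

import pandas as pd

from czscaling import aggregate_to_units, assign_region, write_units_csv

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    data = ROOT / "data"
    pills = pd.read_csv(data / "county_pills.csv", dtype={"county_fips": str})
    pops = pd.read_csv(data / "county_population.csv", dtype={"county_fips": str})
    xwalk = pd.read_csv(data / "crosswalk.csv", dtype={"county_fips": str})

    units = assign_region(aggregate_to_units(pills, pops, xwalk,
                                             window=(2010, 2010)))
    truth = pd.read_csv(data / "units_truth.csv")
    merged = units.merge(truth, on="unit_id", suffixes=("", "_true"))
    exact = (merged["pills_total"] == merged["pills_total_true"]).all()

    write_units_csv(units.drop(columns="state_pops"), ROOT / "units.csv")
    print(f"aggregated {len(units)} units; pill totals match truth exactly: {exact}")
    print(units["region"].value_counts().to_string())
    print(f"wrote {ROOT / 'units.csv'}")


if __name__ == "__main__":
    main()
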