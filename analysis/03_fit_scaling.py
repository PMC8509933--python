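#!/usr/bin/env python
"""Fit the scaling models: single regime, knot search, spline, strata.

On the aggregated unit table this fits (i) the one-slope power law,
(ii) the two-regime spline with the knot chosen by exhaustive profile
search, compares the two by AIC, classifies each slope's scaling regime,
then repeats the spline fit adjusted for region dummies and stratified by
region.  Writes results/fits.json and the knot-search profile.
"""
import json
from pathlib import Path

import numpy as np

from czscaling import (
    classify_regime, compare_aic, fit_piecewise, fit_power_law,
    fit_stratified, make_loglog, percentile_of, read_units_csv, search_knot,
)
from czscaling.scaling import fit_to_dict

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    units = read_units_csv(ROOT / "units.csv")
    frame = make_loglog(units)
    pops = np.exp(frame["x"].to_numpy())

    single = fit_power_law(frame)
    searched = search_knot(frame)
    spline = searched.fit
    aic_spline, aic_single, delta = compare_aic(spline, single)

    print(f"single regime: beta={single.beta:.3f} "
          f"CI=({single.beta_ci[0]:.3f}, {single.beta_ci[1]:.3f}) "
          f"-> {classify_regime(single.beta, single.beta_ci).regime}")
    print(f"knot search:   knot={searched.knot:,.0f} "
          f"({percentile_of(searched.knot, pops):.1f}th population percentile)")
    print(f"spline:        beta1={spline.beta1:.3f} beta2={spline.beta2:.3f} "
          f"regimes: {classify_regime(spline.beta1, spline.beta1_ci).regime} / "
          f"{classify_regime(spline.beta2, spline.beta2_ci).regime}")
    print(f"AIC:           spline {aic_spline:.1f} vs single {aic_single:.1f} "
          f"(delta {delta:.1f}; spline preferred: {delta < 0})")

    adjusted = fit_piecewise(frame, searched.knot, covariates=["region"])
    strata = fit_stratified(frame, by="region", knot=searched.knot)
    for region, fit in strata.fits.items():
        print(f"  {region:<10} n={fit.n:<4} beta1={fit.beta1:.2f} "
              f"beta2={fit.beta2:.2f}")
    for region, reason in strata.skipped.items():
        print(f"  {region}: skipped ({reason})")

    report = {
        "single": fit_to_dict(single),
        "spline": fit_to_dict(spline),
        "adjusted_for_region": fit_to_dict(adjusted),
        "stratified": {r: fit_to_dict(f) for r, f in strata.fits.items()},
        "knot_percentile": percentile_of(searched.knot, pops),
        "aic": {"spline": aic_spline, "single": aic_single, "delta": delta},
    }
    with open(ROOT / "fits.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    searched.profile.to_csv(ROOT / "knot_profile.csv", index=False)
    print(f"wrote {ROOT / 'fits.json'} and knot_profile.csv")


if __name__ == "__main__":
    main()
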