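import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from czscaling import (
    SyntheticConfig,
    classify_regime,
    compare_aic,
    fit_piecewise,
    fit_power_law,
    fit_stratified,
    generate,
    make_loglog,
    percentile_of,
    search_knot,
)
from czscaling.scaling import FitError, default_knot_candidates

from conftest import ols_oracle


def _frame(x, y):
    return pd.DataFrame({"unit_id": [f"u{i}" for i in range(len(x))],
                         "x": np.asarray(x, float), "y": np.asarray(y, float)})


# ---------------------------------------------------------------- single regime

def test_exact_line_recovered():
    x = np.linspace(1, 10, 10)
    fit = fit_power_law(_frame(x, 2.0 + 1.0 * x))
    assert fit.alpha == pytest.approx(2.0, abs=1e-10)
    assert fit.beta == pytest.approx(1.0, abs=1e-10)
    assert fit.sigma == pytest.approx(0.0, abs=1e-8)


def test_ols_matches_closed_form_sums():
    """beta equals (n Sxy - Sx Sy) / (n Sxx - Sx^2) on 5 hand-set pairs."""
    x = np.array([1.0, 2.0, 3.5, 5.0, 8.0])
    y = np.array([2.1, 2.9, 4.2, 5.8, 8.3])
    n, sx, sy = len(x), x.sum(), y.sum()
    sxy, sxx = (x * y).sum(), (x * x).sum()
    beta_exp = (n * sxy - sx * sy) / (n * sxx - sx ** 2)
    alpha_exp = (sy - beta_exp * sx) / n
    fit = fit_power_law(_frame(x, y))
    assert fit.beta == pytest.approx(beta_exp, rel=1e-12)
    assert fit.alpha == pytest.approx(alpha_exp, rel=1e-12)


def test_power_law_preconditions():
    with pytest.raises(FitError):
        fit_power_law(_frame([1, 2], [1, 2]))
    frame = _frame([3.0] * 5, [1, 2, 3, 4, 5])  # constant x: rank deficient
    with pytest.raises(FitError):
        fit_power_law(frame)


# ------------------------------------------------------------------- piecewise

def test_noiseless_piecewise_recovery():
    """Noise-free two-regime data returns the generating parameters."""
    cfg = SyntheticConfig(n_units=100, sigma_noise=0.0, seed=3)
    frame = make_loglog(generate(cfg).units)
    fit = fit_piecewise(frame, cfg.knot_true)
    assert fit.alpha == pytest.approx(cfg.alpha_true, abs=1e-5)
    assert fit.beta1 == pytest.approx(cfg.beta1_true, abs=1e-6)
    assert fit.beta2 == pytest.approx(cfg.beta2_true, abs=1e-6)


def test_piecewise_matches_basis_matrix_oracle(small_frame):
    """Coefficients equal normal equations on the explicit 3-column basis."""
    knot = 1e5
    fit = fit_piecewise(small_frame, knot)
    x = small_frame["x"].to_numpy()
    ln_k = np.log(knot)
    X = np.column_stack([np.ones_like(x), x,
                         np.where(x > ln_k, x - ln_k, 0.0)])
    coef = ols_oracle(X, small_frame["y"].to_numpy())
    assert fit.alpha == pytest.approx(coef[0], rel=1e-8)
    assert fit.beta1 == pytest.approx(coef[1], rel=1e-8)
    assert fit.beta2 == pytest.approx(coef[1] + coef[2], rel=1e-8)


def test_piecewise_side_counts_and_preconditions(small_frame):
    fit = fit_piecewise(small_frame, 1e5)
    assert fit.n_below + fit.n_above == fit.n
    with pytest.raises(FitError):
        fit_piecewise(small_frame, 1e9)        # outside range
    with pytest.raises(FitError):
        fit_piecewise(small_frame, 1.6e4)      # <2 points below


def test_point_at_knot_counts_below():
    x = np.log(np.array([1e4, 3e4, 8e4, 1e5, 3e5, 1e6]))
    fit = fit_piecewise(_frame(x, 2 + x), 1e5)
    assert fit.n_below == 4


# ------------------------------------------------------------------ knot search

def test_noiseless_search_finds_true_knot():
    """With the true knot among the observed populations, search is exact."""
    pops = np.array([1e4, 2e4, 4e4, 82363.0, 2e5, 5e5, 1e6, 5e6])
    x = np.log(pops)
    cfg = SyntheticConfig(sigma_noise=0.0)
    from czscaling.synthetic import piecewise_mean
    frame = _frame(x, piecewise_mean(cfg, x))
    result = search_knot(frame, candidates=pops[1:-1])
    assert result.knot == pytest.approx(82363.0)


def test_search_matches_exhaustive_rss_oracle():
    """Selected knot equals the literal argmin of RSS over the grid."""
    rng = np.random.default_rng(11)
    pops = np.exp(rng.uniform(np.log(1e4), np.log(1e7), 20))
    x = np.log(pops)
    from czscaling.synthetic import piecewise_mean
    y = piecewise_mean(SyntheticConfig(), x) + rng.normal(0, 0.3, 20)
    frame = _frame(x, y)

    best_rss, best_k = np.inf, None
    for k in np.sort(pops):
        ln_k = np.log(k)
        if (x < ln_k).sum() < 2 or (x > ln_k).sum() < 2:
            continue
        X = np.column_stack([np.ones_like(x), x,
                             np.where(x > ln_k, x - ln_k, 0.0)])
        coef = ols_oracle(X, y)
        rss = float(np.sum((y - X @ coef) ** 2))
        if rss < best_rss - 1e-12:
            best_rss, best_k = rss, k

    result = search_knot(frame, candidates=pops)
    assert result.knot == pytest.approx(best_k)
    assert len(result.profile) > 0
    assert result.profile["rss"].min() == pytest.approx(best_rss, rel=1e-9)


def test_default_candidate_grid_is_interior(default_frame):
    pops = np.exp(default_frame["x"].to_numpy())
    cands = default_knot_candidates(default_frame)
    lo, hi = np.percentile(pops, [5, 95])
    assert cands.min() > lo and cands.max() < hi


def test_search_all_infeasible_is_hard_error(small_frame):
    with pytest.raises(FitError):
        search_knot(small_frame, candidates=np.array([1.001e4]))


# -------------------------------------------------------------- AIC & regimes

def test_aic_arithmetic_and_identity(small_frame):
    """AIC = -2 loglik + 2k with sigma counted among the k parameters."""
    single = fit_power_law(small_frame)
    spline = fit_piecewise(small_frame, 1e5)
    assert single.aic == pytest.approx(-2 * single.loglik + 2 * 3)
    assert spline.aic == pytest.approx(-2 * spline.loglik + 2 * 4)
    a, b, delta = compare_aic(spline, spline)
    assert delta == 0.0 and a == b


def test_compare_aic_rejects_mismatched_data(small_frame, default_frame):
    with pytest.raises(FitError):
        compare_aic(fit_power_law(small_frame), fit_power_law(default_frame))


@pytest.mark.parametrize("beta,ci,expected", [
    (1.36, (1.23, 1.50), "superlinear"),
    (0.92, (0.88, 0.95), "sublinear"),
    (1.00, (0.93, 1.06), "linear"),
])
def test_regime_classification(beta, ci, expected):
    assert classify_regime(beta, ci).regime == expected


# ------------------------------------------------------------- stratification

def test_single_stratum_identity(default_frame):
    frame = default_frame.copy()
    frame["stratum"] = "all"
    strat = fit_stratified(frame, by="stratum", knot=82363.0)
    whole = fit_piecewise(default_frame, 82363.0)
    only = strat.fits["all"]
    assert only.beta1 == pytest.approx(whole.beta1)
    assert only.beta2 == pytest.approx(whole.beta2)
    assert strat.skipped == {}


def test_stratified_recovers_per_region_slopes():
    """Four regions with distinct generating slopes are each recovered."""
    rng = np.random.default_rng(21)
    frames = []
    slopes = {"Midwest": 1.42, "Northeast": 1.05, "South": 1.17, "West": 1.39}
    for region, b1 in slopes.items():
        cfg = SyntheticConfig(n_units=300, beta1_true=b1, sigma_noise=0.3,
                              seed=int(rng.integers(2**31)))
        frame = make_loglog(generate(cfg).units)
        frame["region"] = region
        frames.append(frame)
    data = pd.concat(frames, ignore_index=True)
    strat = fit_stratified(data, by="region", knot=82363.0)
    for region, b1 in slopes.items():
        assert strat.fits[region].beta1 == pytest.approx(b1, abs=0.1)
        assert strat.fits[region].beta2 == pytest.approx(0.92, abs=0.06)


def test_stratified_reports_infeasible_strata(default_frame):
    frame = default_frame.copy()
    frame["stratum"] = "big"
    frame.loc[frame.index[:3], "stratum"] = "tiny"
    strat = fit_stratified(frame, by="stratum", knot=82363.0)
    assert "tiny" in strat.skipped and "big" in strat.fits


# ----------------------------------------------------------------- percentile

def test_percentile_midpoint_rule():
    vals = list(range(20))
    assert percentile_of(0, vals) == pytest.approx(100 * 0.5 / 20)
    # counting oracle on a hand-set list with ties
    sample = [1, 2, 2, 3, 5, 5, 5, 8, 9, 10]
    below = sum(v < 5 for v in sample)
    equal = sum(v == 5 for v in sample)
    assert percentile_of(5, sample) == pytest.approx(
        100 * (below + 0.5 * equal) / len(sample))


@settings(derandomize=True, max_examples=100, deadline=None)
@given(st.lists(st.floats(1e3, 1e8), min_size=1, max_size=50),
       st.floats(1e3, 1e8))
def test_percentile_bounds_and_monotonicity(pops, value):
    p = percentile_of(value, pops)
    assert 0.0 <= p <= 100.0
    # adding a value strictly below can only push the percentile up
    assert percentile_of(value, pops + [value / 2 - 1]) >= p


@settings(derandomize=True, max_examples=100, deadline=None)
@given(st.floats(0.2, 3.0), st.floats(0.0, 1.0), st.floats(0.0, 1.0))
def test_widening_ci_moves_regime_toward_linear(beta, pad_lo, pad_hi):
    narrow = (beta - 0.01, beta + 0.01)
    wide = (narrow[0] - pad_lo, narrow[1] + pad_hi)
    labels = {classify_regime(beta, narrow).regime,
              classify_regime(beta, wide).regime}
    # widening can flip a verdict to linear, never to the opposite verdict
    assert labels != {"sublinear", "superlinear"}


# ------------------------------------------------------------------ properties

def test_scale_invariance(default_frame):
    """Multiplying all Y by c shifts alpha by ln c and nothing else."""
    c = 7.3
    shifted = default_frame.copy()
    shifted["y"] = shifted["y"] + np.log(c)

    f0, f1 = fit_power_law(default_frame), fit_power_law(shifted)
    assert f1.alpha - f0.alpha == pytest.approx(np.log(c), rel=1e-9)
    assert f1.beta == pytest.approx(f0.beta, rel=1e-12)
    assert f1.sigma == pytest.approx(f0.sigma, rel=1e-9)
    assert f1.beta_ci == pytest.approx(f0.beta_ci, rel=1e-9)

    p0 = fit_piecewise(default_frame, 82363.0)
    p1 = fit_piecewise(shifted, 82363.0)
    assert p1.beta1 == pytest.approx(p0.beta1, rel=1e-10)
    assert p1.beta2 == pytest.approx(p0.beta2, rel=1e-10)
    # delta-AIC between spline and line is scale invariant too
    d0 = compare_aic(p0, f0)[2]
    d1 = compare_aic(p1, f1)[2]
    assert d1 == pytest.approx(d0, abs=1e-8)


def test_spline_nests_single_regime(default_frame):
    """Extra hinge column can only reduce RSS / raise the log-likelihood."""
    single = fit_power_law(default_frame)
    spline = fit_piecewise(default_frame, 82363.0)
    assert spline.loglik >= single.loglik - 1e-9


def test_continuity_at_knot(default_frame):
    fit = fit_piecewise(default_frame, 82363.0)
    ln_k = np.log(fit.knot)
    for delta in (1e-6, 1e-9, 1e-12):
        below = fit.predict(np.array([ln_k - delta]))[0]
        above = fit.predict(np.array([ln_k + delta]))[0]
        assert abs(above - below) <= (2 * abs(fit.beta1) + abs(fit.hinge)) * delta + 1e-12


def test_hinge_ci_covers_zero_when_single_regime():
    """Data generated with beta1 == beta2: hinge CI covers 0 ~95% of the time."""
    covered = 0
    reps = 500
    for s in range(reps):
        cfg = SyntheticConfig(n_units=200, beta1_true=1.1, beta2_true=1.1,
                              sigma_noise=0.3, seed=90_000 + s)
        frame = make_loglog(generate(cfg).units)
        fit = fit_piecewise(frame, cfg.knot_true)
        if fit.hinge_ci[0] <= 0.0 <= fit.hinge_ci[1]:
            covered += 1
    assert covered / reps == pytest.approx(0.95, abs=0.03)


def test_recovery_error_shrinks_with_n_and_noise():
    """RMSE of the slope estimates falls as n grows and as noise vanishes."""
    def rmse(n, sigma, reps=120, base=50_000):
        errs = []
        for s in range(reps):
            cfg = SyntheticConfig(n_units=n, sigma_noise=sigma, seed=base + s)
            frame = make_loglog(generate(cfg).units)
            fit = fit_piecewise(frame, cfg.knot_true)
            errs.append((fit.beta1 - cfg.beta1_true) ** 2
                        + (fit.beta2 - cfg.beta2_true) ** 2)
        return float(np.sqrt(np.mean(errs)))

    ladder_n = [rmse(n, 0.4, base=60_000) for n in (50, 200, 1000)]
    assert ladder_n[0] > ladder_n[1] > ladder_n[2]
    ladder_s = [rmse(200, s, base=70_000) for s in (0.8, 0.4, 0.1)]
    assert ladder_s[0] > ladder_s[1] > ladder_s[2]
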