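"""Power-law scaling fits on log-log data.

The urban-scaling model relates an outcome count Y (here, opioid pills)
to unit population N through Y ~ N^beta, estimated by OLS on

    ln(Y_i) = alpha + beta * ln(N_i) + eps_i .

A two-regime variant replaces the single slope with a continuous linear
spline in ln(N): slope beta1 below a knot population k and beta2 above it,
via the hinge regressor (ln N - ln k) * 1[N > k].  The knot is chosen by
profiling the Gaussian log-likelihood (equivalently the residual sum of
squares) over candidate populations.  Model comparison uses AIC with the
full Gaussian log-likelihood and the residual variance counted as an
estimated parameter.  beta > 1 is superlinear scaling (disproportionately
more pills in larger units), beta < 1 sublinear.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm


class FitError(ValueError):
    """Raised when a dataset violates a fit precondition."""


def make_loglog(units: pd.DataFrame, carry: tuple[str, ...] = ("region", "stratum")
                ) -> pd.DataFrame:
    """Build the log-log frame (unit_id, x=ln pop_mean, y=ln pills_total).

    Rows with non-positive pills or population cannot enter a log-scale
    fit and are dropped with a warning.
    """
    import logging
    bad = (units["pills_total"] <= 0) | (units["pop_mean"] <= 0)
    if bad.any():
        logging.getLogger(__name__).warning(
            "dropping %d unit(s) with non-positive pills or population: %s",
            int(bad.sum()), units.loc[bad, "unit_id"].tolist())
    kept = units.loc[~bad]
    frame = pd.DataFrame({
        "unit_id": kept["unit_id"].to_numpy(),
        "x": np.log(kept["pop_mean"].to_numpy(dtype=float)),
        "y": np.log(kept["pills_total"].to_numpy(dtype=float)),
    })
    for col in carry:
        if col in kept.columns:
            frame[col] = kept[col].to_numpy()
    return frame


def _covariate_design(frame: pd.DataFrame, covariates) -> tuple[np.ndarray, list[str]]:
    """Expand covariate names into numeric design columns.

    Categorical (non-numeric) columns become sorted dummy columns with the
    alphabetically first level as the reference.
    """
    cols, names = [], []
    for cov in covariates or ():
        if cov not in frame.columns:
            raise FitError(f"covariate {cov!r} not in data")
        col = frame[cov]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(dtype=float))
            names.append(cov)
        else:
            levels = sorted(pd.unique(col.astype(str)))
            for lev in levels[1:]:
                cols.append((col.astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{cov}[{lev}]")
    if not cols:
        return np.empty((len(frame), 0)), []
    return np.column_stack(cols), names


def _check_frame(frame: pd.DataFrame, min_n: int) -> None:
    x = frame["x"].to_numpy(dtype=float)
    y = frame["y"].to_numpy(dtype=float)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise FitError("non-finite values in log-log data")
    if len(frame) < min_n:
        raise FitError(f"need at least {min_n} rows, got {len(frame)}")


def _ols(y: np.ndarray, X: np.ndarray, names: list[str]):
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise FitError("rank-deficient design matrix")
    res = sm.OLS(y, pd.DataFrame(X, columns=names)).fit()
    return res


@dataclass(frozen=True)
class PowerLawFit:
    """Single-regime fit: ln Y = alpha + beta ln N (+ covariates)."""
    alpha: float
    beta: float
    beta_ci: tuple[float, float]
    sigma: float            # residual SD with n - p df correction
    loglik: float           # maximized Gaussian log-likelihood, constants included
    aic: float              # -2 loglik + 2 (p + 1), sigma counted
    n: int
    covariate_coefs: dict[str, float] = field(default_factory=dict)
    unit_ids: tuple = field(default=(), compare=False)
    fitted: np.ndarray = field(default=None, repr=False, compare=False)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Mean log-outcome at log-population x, covariates at reference."""
        return self.alpha + self.beta * np.asarray(x, dtype=float)


@dataclass(frozen=True)
class PiecewiseFit:
    """Continuous two-regime fit with a single knot at population ``knot``."""
    alpha: float
    beta1: float
    beta2: float
    knot: float
    beta1_ci: tuple[float, float]
    beta2_ci: tuple[float, float]
    hinge: float            # beta2 - beta1
    hinge_ci: tuple[float, float]
    sigma: float
    loglik: float
    aic: float
    n: int
    n_below: int            # points with N <= knot
    n_above: int
    covariate_coefs: dict[str, float] = field(default_factory=dict)
    unit_ids: tuple = field(default=(), compare=False)
    fitted: np.ndarray = field(default=None, repr=False, compare=False)

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        ln_k = np.log(self.knot)
        return (self.alpha + self.beta1 * x
                + self.hinge * np.where(x > ln_k, x - ln_k, 0.0))


@dataclass(frozen=True)
class RegimeClass:
    regime: str                      # sublinear | linear | superlinear
    basis: tuple[float, float]       # the CI the call was decided on


def fit_power_law(frame: pd.DataFrame, covariates=None) -> PowerLawFit:
    """OLS fit of the single-regime scaling model.

    95% CI for beta from the t distribution with n - p degrees of freedom.
    """
    _check_frame(frame, 3)
    x = frame["x"].to_numpy(dtype=float)
    y = frame["y"].to_numpy(dtype=float)
    C, cov_names = _covariate_design(frame, covariates)
    X = np.column_stack([np.ones_like(x), x, C])
    names = ["const", "x"] + cov_names
    res = _ols(y, X, names)
    p = X.shape[1]
    n = len(y)
    ci = res.conf_int(alpha=0.05)
    sigma = float(np.sqrt(res.ssr / (n - p)))
    return PowerLawFit(
        alpha=float(res.params["const"]),
        beta=float(res.params["x"]),
        beta_ci=(float(ci.loc["x", 0]), float(ci.loc["x", 1])),
        sigma=sigma,
        loglik=float(res.llf),
        aic=float(-2.0 * res.llf + 2.0 * (p + 1)),
        n=n,
        covariate_coefs={c: float(res.params[c]) for c in cov_names},
        unit_ids=tuple(frame["unit_id"]) if "unit_id" in frame.columns else (),
        fitted=np.asarray(res.fittedvalues, dtype=float),
    )


def fit_piecewise(frame: pd.DataFrame, knot: float, covariates=None) -> PiecewiseFit:
    """OLS fit of the continuous two-slope spline with a fixed knot.

    The hinge regressor is (x - ln k) * 1[x > ln k], so points exactly at
    the knot population belong to the below-knot side; continuity of the
    mean function at ln k holds by construction.  beta2 = beta1 + hinge
    coefficient; its CI comes from the covariance of that linear
    combination (t distribution, n - p df).
    """
    _check_frame(frame, 5)
    x = frame["x"].to_numpy(dtype=float)
    y = frame["y"].to_numpy(dtype=float)
    ln_k = float(np.log(knot))
    if not (x.min() < ln_k < x.max()):
        raise FitError(f"knot {knot} outside the observed population range")
    above = x > ln_k
    strictly_below = x < ln_k
    if strictly_below.sum() < 2 or above.sum() < 2:
        raise FitError(
            f"knot {knot} leaves fewer than 2 points strictly on one side "
            f"({int(strictly_below.sum())} below, {int(above.sum())} above)")
    hinge_col = np.where(above, x - ln_k, 0.0)
    C, cov_names = _covariate_design(frame, covariates)
    X = np.column_stack([np.ones_like(x), x, hinge_col, C])
    names = ["const", "x", "hinge"] + cov_names
    res = _ols(y, X, names)
    p = X.shape[1]
    n = len(y)

    beta1 = float(res.params["x"])
    gamma = float(res.params["hinge"])
    beta2 = beta1 + gamma
    cov = res.cov_params()
    var_b2 = float(cov.loc["x", "x"] + cov.loc["hinge", "hinge"]
                   + 2.0 * cov.loc["x", "hinge"])
    tcrit = float(scipy.stats.t.ppf(0.975, n - p))
    se_b2 = float(np.sqrt(var_b2))
    ci = res.conf_int(alpha=0.05)
    return PiecewiseFit(
        alpha=float(res.params["const"]),
        beta1=beta1,
        beta2=beta2,
        knot=float(knot),
        beta1_ci=(float(ci.loc["x", 0]), float(ci.loc["x", 1])),
        beta2_ci=(beta2 - tcrit * se_b2, beta2 + tcrit * se_b2),
        hinge=gamma,
        hinge_ci=(float(ci.loc["hinge", 0]), float(ci.loc["hinge", 1])),
        sigma=float(np.sqrt(res.ssr / (n - p))),
        loglik=float(res.llf),
        aic=float(-2.0 * res.llf + 2.0 * (p + 1)),
        n=n,
        n_below=int((~above).sum()),
        n_above=int(above.sum()),
        covariate_coefs={c: float(res.params[c]) for c in cov_names},
        unit_ids=tuple(frame["unit_id"]) if "unit_id" in frame.columns else (),
        fitted=np.asarray(res.fittedvalues, dtype=float),
    )


@dataclass(frozen=True)
class KnotSearchResult:
    knot: float
    fit: PiecewiseFit
    profile: pd.DataFrame = field(compare=False)  # candidate, loglik, rss


def default_knot_candidates(frame: pd.DataFrame,
                            lower_pct: float = 5.0,
                            upper_pct: float = 95.0) -> np.ndarray:
    """Observed populations strictly between two population percentiles."""
    pops = np.exp(frame["x"].to_numpy(dtype=float))
    lo, hi = np.percentile(pops, [lower_pct, upper_pct])
    cands = np.unique(pops[(pops > lo) & (pops < hi)])
    return cands


def search_knot(frame: pd.DataFrame,
                candidates: np.ndarray | None = None,
                covariates=None) -> KnotSearchResult:
    """Profile the knot over a candidate grid and refit at the best value.

    Each candidate is scored by the maximized Gaussian log-likelihood of
    the spline model (a monotone transform of its residual sum of
    squares, so the argmax is the RSS argmin); ties go to the smallest
    knot.  The profile over all feasible candidates is returned for
    diagnostics.
    """
    _check_frame(frame, 5)
    if candidates is None:
        candidates = default_knot_candidates(frame)
    candidates = np.sort(np.asarray(candidates, dtype=float))
    if candidates.size == 0:
        raise FitError("empty knot candidate grid")
    x = frame["x"].to_numpy(dtype=float)
    y = frame["y"].to_numpy(dtype=float)
    C, _ = _covariate_design(frame, covariates)
    n = len(y)
    ones = np.ones_like(x)

    recs = []
    best = None
    for k in candidates:
        ln_k = np.log(k)
        above = x > ln_k
        if (x < ln_k).sum() < 2 or above.sum() < 2 or not (x.min() < ln_k < x.max()):
            continue
        X = np.column_stack([ones, x, np.where(above, x - ln_k, 0.0), C])
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ coef) ** 2))
        llf = -0.5 * n * (np.log(2.0 * np.pi) + np.log(rss / n) + 1.0)
        recs.append((float(k), llf, rss))
        if best is None or llf > best[1]:       # strict >: ties keep smaller knot
            best = (float(k), llf)
    if best is None:
        raise FitError("no feasible knot candidate (all leave <2 points on a side)")
    profile = pd.DataFrame(recs, columns=["candidate", "loglik", "rss"])
    fit = fit_piecewise(frame, best[0], covariates=covariates)
    return KnotSearchResult(knot=best[0], fit=fit, profile=profile)


def compare_aic(fit_a, fit_b) -> tuple[float, float, float]:
    """Return (aic_a, aic_b, aic_a - aic_b); both fits must share the data."""
    if fit_a.n != fit_b.n:
        raise FitError(f"fits on different data: n={fit_a.n} vs n={fit_b.n}")
    if fit_a.unit_ids and fit_b.unit_ids and set(fit_a.unit_ids) != set(fit_b.unit_ids):
        raise FitError("fits on different unit sets")
    return fit_a.aic, fit_b.aic, fit_a.aic - fit_b.aic


def classify_regime(beta: float, ci: tuple[float, float]) -> RegimeClass:
    """Label a scaling coefficient by where its 95% CI sits relative to 1."""
    lo, hi = float(ci[0]), float(ci[1])
    if lo > hi:
        raise FitError(f"invalid interval ({lo}, {hi})")
    if lo > 1.0:
        regime = "superlinear"
    elif hi < 1.0:
        regime = "sublinear"
    else:
        regime = "linear"
    return RegimeClass(regime=regime, basis=(lo, hi))


@dataclass(frozen=True)
class StratifiedFits:
    fits: dict
    skipped: dict[str, str]   # stratum -> reason it could not be fit


def fit_stratified(frame: pd.DataFrame, by: str,
                   knot: float | None = None,
                   covariates=None) -> StratifiedFits:
    """Fit an independent model inside each stratum of column ``by``.

    With ``knot`` set the piecewise model is fit, otherwise the
    single-regime model.  Strata violating a fit precondition are reported
    in ``skipped`` rather than silently dropped.
    """
    if by not in frame.columns:
        raise FitError(f"stratum column {by!r} not in data")
    fits, skipped = {}, {}
    for stratum, grp in frame.groupby(by, sort=True):
        try:
            if knot is None:
                fits[stratum] = fit_power_law(grp, covariates=covariates)
            else:
                fits[stratum] = fit_piecewise(grp, knot, covariates=covariates)
        except FitError as exc:
            skipped[stratum] = str(exc)
    return StratifiedFits(fits=fits, skipped=skipped)


def percentile_of(value: float, populations) -> float:
    """Empirical percentile of ``value`` in a population sample.

    Midpoint rule: 100 * (#below + 0.5 * #equal) / n.
    """
    pops = np.asarray(list(populations), dtype=float)
    if pops.size == 0:
        raise FitError("empty population list")
    below = float(np.sum(pops < value))
    equal = float(np.sum(pops == value))
    return 100.0 * (below + 0.5 * equal) / pops.size


def fit_to_dict(fit) -> dict:
    """Flatten a fit dataclass to JSON-serializable key-value pairs."""
    d = dataclasses.asdict(fit)
    d.pop("fitted", None)
    d.pop("unit_ids", None)
    for key, val in list(d.items()):
        if isinstance(val, tuple):
            d[key] = list(val)
    d["model"] = type(fit).__name__
    return d
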