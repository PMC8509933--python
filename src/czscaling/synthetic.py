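"""Synthetic spatial-unit data with the generative structure the fits assume.

Units get heavy-tailed populations (default log-uniform over the commuting
-zone range 1e4 to 2e7 people), pill counts from the continuous two-regime
power law

    ln Y_i = alpha + beta1 ln N_i + (beta2 - beta1)(ln N_i - ln k) 1[N_i > k] + eps_i,

with eps ~ Normal(0, sigma_noise^2), rounded to integer counts (floor 1),
plus census-region labels.  Optional disaggregation splits each unit into
counties (Dirichlet population shares, multinomial pill shares), exercising
the aggregation stage end-to-end.  Every dataset stores its generating
config so recovery tests always have the ground truth.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

REGIONS = ("Midwest", "Northeast", "South", "West")
# one representative state per region for synthetic crosswalks
_REGION_STATE = {"Midwest": "OH", "Northeast": "NY", "South": "TX", "West": "CA"}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters; defaults emulate the 607-CZ study sample."""
    n_units: int = 607
    pop_law: str = "log_uniform"            # log_uniform | log_normal | zipf
    pop_params: tuple = (np.log(1e4), np.log(2e7))
    alpha_true: float = 5.0
    beta1_true: float = 1.36
    beta2_true: float = 0.92
    knot_true: float = 82_363.0
    sigma_noise: float = 0.4
    region_weights: tuple = (0.333, 0.063, 0.408, 0.196)
    n_counties_per_unit: tuple | None = None   # inclusive (lo, hi) range
    seed: int = 0

    def validate(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be positive")
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be >= 0")
        if self.pop_law not in ("log_uniform", "log_normal", "zipf"):
            raise ValueError(f"unknown pop_law {self.pop_law!r}")
        if abs(sum(self.region_weights) - 1.0) > 1e-9:
            raise ValueError("region_weights must sum to 1")
        lo, hi = self._ln_support()
        if not (lo <= np.log(self.knot_true) <= hi):
            raise ValueError("knot_true outside the population support")
        if self.n_counties_per_unit is not None:
            a, b = self.n_counties_per_unit
            if a < 1 or b < a:
                raise ValueError("n_counties_per_unit must be a (lo, hi) range, lo >= 1")

    def _ln_support(self) -> tuple[float, float]:
        if self.pop_law == "log_uniform":
            return float(self.pop_params[0]), float(self.pop_params[1])
        return -np.inf, np.inf


@dataclass(frozen=True)
class SyntheticDataset:
    units: pd.DataFrame = field(compare=False)
    truth: SyntheticConfig = None
    injected_outliers: tuple = ()

    @property
    def log_pills_exact(self) -> np.ndarray:
        """ln(Y) before integer rounding (kept for noiseless-limit checks)."""
        return self.units["_ln_pills_exact"].to_numpy(dtype=float)


def _draw_populations(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.pop_law == "log_uniform":
        lo, hi = cfg.pop_params
        return np.exp(rng.uniform(lo, hi, size=cfg.n_units))
    if cfg.pop_law == "log_normal":
        mu, sd = cfg.pop_params
        return np.exp(rng.normal(mu, sd, size=cfg.n_units))
    # zipf: Pareto tail anchored at 1e4, shape from pop_params[0]
    shape = float(cfg.pop_params[0]) if cfg.pop_params else 1.0
    return 1e4 * (1.0 + rng.pareto(shape, size=cfg.n_units))


def piecewise_mean(cfg: SyntheticConfig, ln_pop: np.ndarray) -> np.ndarray:
    """Noise-free model prediction for ln(pills) at the config's truth."""
    ln_k = np.log(cfg.knot_true)
    hinge = np.where(ln_pop > ln_k, ln_pop - ln_k, 0.0)
    return cfg.alpha_true + cfg.beta1_true * ln_pop \
        + (cfg.beta2_true - cfg.beta1_true) * hinge


def generate(cfg: SyntheticConfig) -> SyntheticDataset:
    """Draw a unit table from the config; bit-reproducible under the seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    pops = _draw_populations(cfg, rng)
    ln_pop = np.log(pops)
    eps = rng.normal(0.0, cfg.sigma_noise, size=cfg.n_units)
    ln_pills = piecewise_mean(cfg, ln_pop) + eps
    pills = np.maximum(np.rint(np.exp(ln_pills)), 1.0).astype(np.int64)
    regions = rng.choice(REGIONS, size=cfg.n_units, p=np.asarray(cfg.region_weights))
    units = pd.DataFrame({
        "unit_id": [f"U{i:05d}" for i in range(cfg.n_units)],
        "pills_total": pills,
        "pop_mean": pops,
        "region": regions,
        "stratum": "",
        "n_counties": 1,
        "_ln_pills_exact": ln_pills,
    })
    return SyntheticDataset(units=units, truth=cfg)


def disaggregate_to_counties(dataset: SyntheticDataset,
                             year: int = 2010) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Split units into synthetic counties; aggregation inverts it.

    Populations split by symmetric Dirichlet(1) shares (rounded, floor 1);
    pill counts by a multinomial with probabilities proportional to county
    population shares, so unit pill totals are conserved exactly.

    Returns (pills, populations, crosswalk) frames in the CSV schemas the
    aggregation module reads, all for a one-year study window ``year``.
    """
    cfg = dataset.truth
    if cfg.n_counties_per_unit is None:
        raise ValueError("config has no n_counties_per_unit range")
    lo, hi = cfg.n_counties_per_unit
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    pills_rows, pop_rows, xwalk_rows = [], [], []
    fips_counter = 1001
    for _, row in dataset.units.iterrows():
        n_c = int(rng.integers(lo, hi + 1))
        shares = rng.dirichlet(np.ones(n_c))
        county_pops = np.maximum(np.rint(shares * row["pop_mean"]), 1.0).astype(np.int64)
        county_pills = rng.multinomial(int(row["pills_total"]),
                                       county_pops / county_pops.sum())
        state = _REGION_STATE.get(row["region"], "TX")
        for j in range(n_c):
            fips = f"{fips_counter:05d}"
            fips_counter += 1
            pills_rows.append({"county_fips": fips, "year": year,
                               "pills": int(county_pills[j])})
            pop_rows.append({"county_fips": fips, "year": year,
                             "population": int(county_pops[j])})
            xwalk_rows.append({"county_fips": fips, "unit_id": row["unit_id"],
                               "unit_kind": "CZ", "state": state})
    return (pd.DataFrame(pills_rows), pd.DataFrame(pop_rows),
            pd.DataFrame(xwalk_rows))


def inject_outliers(dataset: SyntheticDataset, k: int, magnitude: float
                    ) -> SyntheticDataset:
    """Displace k random units by ``magnitude`` residual SDs on the log scale.

    ``magnitude`` is signed and in units of the config's sigma_noise.  The
    injected unit ids are recorded on the returned dataset.
    """
    cfg = dataset.truth
    if k >= cfg.n_units:
        raise ValueError("cannot displace every unit")
    if k == 0:
        return dataset
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 13]))
    idx = rng.choice(cfg.n_units, size=k, replace=False)
    units = dataset.units.copy()
    shift = magnitude * cfg.sigma_noise
    ln_pills = units["_ln_pills_exact"].to_numpy(dtype=float).copy()
    ln_pills[idx] += shift
    units["_ln_pills_exact"] = ln_pills
    units["pills_total"] = np.maximum(np.rint(np.exp(ln_pills)), 1.0).astype(np.int64)
    ids = tuple(sorted(units["unit_id"].iloc[idx]))
    return SyntheticDataset(units=units, truth=cfg, injected_outliers=ids)
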