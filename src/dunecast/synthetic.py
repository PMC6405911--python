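"""Synthetic world generator for the dune-disturbance pipeline.

Real applications of this pipeline train on station climate records, a
dendrochronological growth index, documentary grazing-pressure and fire-scar
records, and luminescence (OSL) dated sand-deposition events.  None of those
records ship with the package, so this module generates statistically
analogous stand-ins with *known* ground truth:

* climate (growing-season precipitation, average max/min temperature) as
  long-term means plus AR(1) noise,
* a tree-ring growth index responding linearly to precipitation (+) and
  maximum temperature (−),
* piecewise-constant grazing-pressure regimes on an ordinal 1/2/3 scale,
* binary wildfire occurrence whose probability rises with temperature,
* sediment-deposition events triggered when a lagged disturbance "mobility"
  score crosses a threshold, then degraded the way a dune records them:
  events are randomly censored (erosional loss) and dated with Gaussian
  error.

Every generated object is a pure function of the configuration, including
its seed; each site draws from an independent child stream of the master
seed, so adding sites never perturbs existing ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .series import AnnualSeries, ConfigurationError, InputError, require_same_grid

# default mobility weights: standardized drought and heat stress, ordinal
# grazing excess over the low level, and a fire spike.  Calibrated once so
# the default world produces roughly 5-10 deposition events per 400 years.
DEFAULT_MOBILITY_WEIGHTS = {
    "drought": 1.0,
    "temperature": 0.6,
    "grazing": 0.25,
    "fire": 0.5,
}


@dataclass
class TreeRingParams:
    """Linear tree-ring response: index = intercept + b_p*precip - b_t*tmax + noise."""
    intercept: float = 2000.0
    precip_coef: float = 50.0     # index units per inch
    tmax_coef: float = 20.0       # index units per degF (entered with minus sign)
    noise_sd: float = 50.0


@dataclass
class DepositionParams:
    """Event generation and taphonomic degradation parameters."""
    threshold: float = 2.7          # on the standardized mobility scale
    response_lag: int = 2           # years between disturbance and deposition
    dating_error_sd: float = 10.0   # 1-sigma OSL dating error, years
    censor_prob: float = 0.3        # per-event probability of erosional loss
    weights: dict = field(default_factory=lambda: dict(DEFAULT_MOBILITY_WEIGHTS))


@dataclass
class WorldConfig:
    """Full configuration of one synthetic world.

    ``years`` is the inclusive historical range (default 1590-1997, the
    ~400-year window a stacked dune chronology covers). ``ar_phi`` is the
    lag-1 autocorrelation shared by the three climate variables; ``ar_order``
    exists so higher-order noise can be exercised but defaults to 1.
    """
    seed: int = 0
    years: tuple[int, int] = (1590, 1997)
    precip_mean: float = 18.0       # inches, growing season total
    tmax_mean: float = 82.0         # degF
    tmin_mean: float = 55.0         # degF
    ar_phi: float = 0.3
    ar_order: int = 1
    precip_sd: float = 3.0
    tmax_sd: float = 2.0
    tmin_sd: float = 2.0
    treering: TreeRingParams = field(default_factory=TreeRingParams)
    grazing_regimes: tuple = ((1590, 1.0), (1850, 2.0), (1930, 3.0), (1960, 2.0))
    fire_base_prob: float = 0.03
    fire_temp_coeff: float = 0.02   # probability per degF above the mean
    deposition: DepositionParams = field(default_factory=DepositionParams)
    n_sites: int = 6

    def __post_init__(self) -> None:
        y0, y1 = self.years
        if y1 - y0 + 1 < 60:
            raise ConfigurationError("year range must span at least 60 years")
        if not (0.0 <= self.ar_phi < 1.0):
            raise ConfigurationError("ar_phi must be in [0, 1)")
        if self.ar_order < 1:
            raise ConfigurationError("ar_order must be >= 1")
        for sd in (self.precip_sd, self.tmax_sd, self.tmin_sd,
                   self.treering.noise_sd, self.deposition.dating_error_sd):
            if sd < 0:
                raise ConfigurationError("standard deviations must be >= 0")
        if not (0.0 <= self.deposition.censor_prob <= 1.0):
            raise ConfigurationError("censor_prob must be in [0, 1]")
        if self.n_sites < 1:
            raise ConfigurationError("n_sites must be >= 1")
        starts = [r[0] for r in self.grazing_regimes]
        if starts != sorted(starts):
            raise ConfigurationError("grazing regimes must be sorted by start year")

    @property
    def year_grid(self) -> np.ndarray:
        return np.arange(self.years[0], self.years[1] + 1)


@dataclass(frozen=True)
class OSLAgeRecord:
    """One luminescence-dated deposition event."""
    site: str
    age_year: float      # recorded calendar year AD (true year + dating error)
    sigma_years: float   # 1-sigma dating uncertainty


def _rng(seed_key) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed_key))


def _ar_noise(n: int, phi: float, sd: float, rng: np.random.Generator,
              order: int = 1, burn: int = 100) -> np.ndarray:
    """Stationary AR(order) noise with all lag coefficients equal to phi/order."""
    if sd == 0.0:
        return np.zeros(n)
    coefs = np.full(order, phi / order)
    eps = rng.normal(0.0, sd, size=n + burn)
    x = np.zeros(n + burn)
    for t in range(order, n + burn):
        x[t] = coefs @ x[t - order:t][::-1] + eps[t]
    return x[burn:]


def gen_climate(config: WorldConfig) -> dict[str, AnnualSeries]:
    """Generate precipitation, tmax and tmin: mean + AR noise, shared phi."""
    years = config.year_grid
    n = years.size
    out = {}
    specs = [
        ("precip", config.precip_mean, config.precip_sd, "inches"),
        ("tmax", config.tmax_mean, config.tmax_sd, "degF"),
        ("tmin", config.tmin_mean, config.tmin_sd, "degF"),
    ]
    for i, (name, mean, sd, units) in enumerate(specs):
        rng = _rng((config.seed, 10 + i))
        vals = mean + _ar_noise(n, config.ar_phi, sd, rng, order=config.ar_order)
        out[name] = AnnualSeries(years, vals, units=units, name=name)
    return out


def gen_tree_ring(climate: dict[str, AnnualSeries],
                  params: TreeRingParams,
                  seed) -> AnnualSeries:
    """Tree-ring growth index: linear climate response plus Gaussian noise.

    index_t = intercept + b_p * precip_t - b_t * tmax_t + eps_t, truncated
    at zero (ring widths cannot be negative).
    """
    years = require_same_grid(climate["precip"], climate["tmax"])
    rng = _rng(seed)
    eps = (rng.normal(0.0, params.noise_sd, size=years.size)
           if params.noise_sd > 0 else np.zeros(years.size))
    vals = (params.intercept
            + params.precip_coef * climate["precip"].values
            - params.tmax_coef * climate["tmax"].values
            + eps)
    return AnnualSeries(years, np.maximum(vals, 0.0), units="index", name="treering")


def gen_grazing(config: WorldConfig) -> AnnualSeries:
    """Piecewise-constant grazing-pressure index over the configured regimes."""
    years = config.year_grid
    vals = np.empty(years.size)
    regimes = list(config.grazing_regimes)
    level = regimes[0][1]
    j = 0
    for i, y in enumerate(years):
        while j + 1 < len(regimes) and y >= regimes[j + 1][0]:
            j += 1
            level = regimes[j][1]
        vals[i] = level
    return AnnualSeries(years, vals, units="index", name="grazing")


def gen_fire(config: WorldConfig, tmax: AnnualSeries) -> AnnualSeries:
    """Binary wildfire series; occurrence probability rises with tmax anomaly."""
    rng = _rng((config.seed, 20))
    p = np.clip(config.fire_base_prob
                + config.fire_temp_coeff * (tmax.values - config.tmax_mean),
                0.0, 1.0)
    vals = (rng.random(tmax.years.size) < p).astype(float)
    return AnnualSeries(tmax.years, vals, units="binary", name="fire")


def mobility_score(climate: dict[str, AnnualSeries],
                   grazing: AnnualSeries,
                   fire: AnnualSeries,
                   config: WorldConfig) -> AnnualSeries:
    """Standardized disturbance pressure driving sediment mobilisation.

    Drought (precip deficit) and heat stress are standardized by their
    innovation SDs; grazing contributes its excess over the low level;
    fire contributes a spike in fire years.
    """
    years = require_same_grid(climate["precip"], climate["tmax"], grazing, fire)
    w = config.deposition.weights
    p_sd = config.precip_sd if config.precip_sd > 0 else 1.0
    t_sd = config.tmax_sd if config.tmax_sd > 0 else 1.0
    score = (w["drought"] * (config.precip_mean - climate["precip"].values) / p_sd
             + w["temperature"] * (climate["tmax"].values - config.tmax_mean) / t_sd
             + w["grazing"] * (grazing.values - 1.0)
             + w["fire"] * fire.values)
    return AnnualSeries(years, score, units="z", name="mobility")


def true_event_years(mobility: AnnualSeries, params: DepositionParams) -> np.ndarray:
    """Deposition years: upward threshold crossings of the mobility score,
    shifted by the response lag and clipped to the grid."""
    m = mobility.values
    above = m > params.threshold
    crossing = above & ~np.concatenate([[False], above[:-1]])
    years = mobility.years[crossing] + params.response_lag
    return years[years <= mobility.end]


def gen_deposition_ages(mobility: AnnualSeries,
                        params: DepositionParams,
                        site: str,
                        site_seed) -> tuple[list[OSLAgeRecord], np.ndarray]:
    """One site's observed OSL age list plus the (shared) true event years.

    Each true event survives erosional censoring with probability
    ``1 - censor_prob``; a surviving event's recorded age is perturbed by
    Normal(0, dating_error_sd).  The reported 1-sigma is dating_error_sd,
    floored at 1 year so downstream density estimation is always defined.
    """
    if mobility.years.size == 0:
        raise InputError("empty driver series")
    truth = true_event_years(mobility, params)
    rng = _rng(site_seed)
    records: list[OSLAgeRecord] = []
    sigma = max(params.dating_error_sd, 1.0)
    for year in truth:
        if rng.random() < params.censor_prob:
            continue
        err = rng.normal(0.0, params.dating_error_sd) if params.dating_error_sd > 0 else 0.0
        records.append(OSLAgeRecord(site=site, age_year=float(year + err),
                                    sigma_years=sigma))
    return records, truth


@dataclass
class World:
    """A fully generated synthetic study area."""
    config: WorldConfig
    climate: dict[str, AnnualSeries]
    treering: AnnualSeries
    grazing: AnnualSeries
    fire: AnnualSeries
    mobility: AnnualSeries
    sites: dict[str, list[OSLAgeRecord]]
    truth_years: np.ndarray

    @property
    def site_names(self) -> list[str]:
        return list(self.sites)


def site_name(i: int) -> str:
    return chr(ord("A") + i) if i < 26 else f"S{i}"


def generate_world(config: WorldConfig) -> World:
    """Generate every pipeline input for one world, with ground truth."""
    climate = gen_climate(config)
    treering = gen_tree_ring(climate, config.treering, (config.seed, 30))
    grazing = gen_grazing(config)
    fire = gen_fire(config, climate["tmax"])
    mob = mobility_score(climate, grazing, fire, config)
    sites = {}
    truth = None
    for i in range(config.n_sites):
        name = site_name(i)
        recs, truth = gen_deposition_ages(mob, config.deposition, name,
                                          (config.seed, 100 + i))
        sites[name] = recs
    return World(config, climate, treering, grazing, fire, mob, sites, truth)


def write_world(world: World, outdir: str | Path) -> None:
    """Write the observed CSV layouts plus a truth manifest.

    Observed files never contain truth columns; ground truth (generator
    parameters and true event years) goes to ``truth.json`` only.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cl = world.climate
    pd.DataFrame({
        "year": cl["precip"].years,
        "precip": cl["precip"].values,
        "tmax": cl["tmax"].values,
        "tmin": cl["tmin"].values,
    }).to_csv(outdir / "climate.csv", index=False)
    for name, s in (("treering", world.treering), ("grazing", world.grazing),
                    ("fire", world.fire)):
        pd.DataFrame({"year": s.years, "value": s.values, "units": s.units}) \
            .to_csv(outdir / f"{name}.csv", index=False)
    rows = [(r.site, r.age_year, r.sigma_years)
            for recs in world.sites.values() for r in recs]
    pd.DataFrame(rows, columns=["site", "age_year", "sigma_years"]) \
        .to_csv(outdir / "osl_ages.csv", index=False)
    truth = {
        "seed": world.config.seed,
        "years": list(world.config.years),
        "true_event_years": [int(y) for y in world.truth_years],
        "deposition_params": {
            "threshold": world.config.deposition.threshold,
            "response_lag": world.config.deposition.response_lag,
            "dating_error_sd": world.config.deposition.dating_error_sd,
            "censor_prob": world.config.deposition.censor_prob,
            "weights": world.config.deposition.weights,
        },
        "treering_params": asdict(world.config.treering),
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))


def read_world_csvs(indir: str | Path) -> dict:
    """Read back the observed CSV layouts written by :func:`write_world`."""
    indir = Path(indir)
    cl = pd.read_csv(indir / "climate.csv")
    out = {
        "climate": {
            "precip": AnnualSeries(cl["year"], cl["precip"], units="inches", name="precip"),
            "tmax": AnnualSeries(cl["year"], cl["tmax"], units="degF", name="tmax"),
            "tmin": AnnualSeries(cl["year"], cl["tmin"], units="degF", name="tmin"),
        }
    }
    for name in ("treering", "grazing", "fire"):
        df = pd.read_csv(indir / f"{name}.csv")
        units = str(df["units"].iloc[0]) if "units" in df else ""
        out[name] = AnnualSeries(df["year"], df["value"], units=units, name=name)
    ages = pd.read_csv(indir / "osl_ages.csv")
    records: dict[str, list[OSLAgeRecord]] = {}
    for _, row in ages.iterrows():
        records.setdefault(str(row["site"]), []).append(
            OSLAgeRecord(str(row["site"]), float(row["age_year"]),
                         float(row["sigma_years"])))
    out["sites"] = records
    return out
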