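"""Hypothetical climate futures and the six disturbance scenarios.

Forecasting drives the trained networks with stylised futures over
1998-2098: a 1998-2014 "measured" segment followed by 84 simulated years.
Two climates are used — climate 1 holds every variable at its long-term
mean plus autoregressive noise fitted to the historical record; climate 2
is identical except that both temperature series ramp linearly to +4.5 degF
by 2098 (a low-emission projection).  Six scenarios combine the two
climates with an optional 10-year grazing-pressure pulse from 2059 and an
optional temperature-triggered wildfire rule (fire in years with average
maximum temperature strictly above 80 degF).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.tsa.ar_model import AutoReg

from .rngutil import derive_seed
from .series import AnnualSeries, ConfigurationError, InputError, concat_years

GRAZING_LEVELS = {"low": 1.0, "moderate": 2.0, "heavy": 3.0}
WARMING_DEGF = 4.5
RAMP_START, RAMP_END = 2015, 2098
PULSE_START, PULSE_YEARS, PULSE_INCREMENT = 2059, 10, 1.0
FIRE_THRESHOLD_F = 80.0
MEASURED_START, MEASURED_END = 1998, 2014


@dataclass
class VariableNoise:
    """Fitted AR noise for one climate variable."""
    mean: float
    coefs: np.ndarray     # AR coefficients, length = order
    innovation_sd: float

    def simulate(self, n: int, rng: np.random.Generator, burn: int = 100) -> np.ndarray:
        """Zero-mean AR noise path of length n (the mean is added by the
        climate builder, not here)."""
        if self.innovation_sd == 0.0 or n == 0:
            return np.zeros(n)
        order = self.coefs.size
        eps = rng.normal(0.0, self.innovation_sd, size=n + burn)
        x = np.zeros(n + burn)
        for t in range(order, n + burn):
            x[t] = self.coefs @ x[t - order:t][::-1] + eps[t]
        return x[burn:]


@dataclass
class ARNoiseModel:
    """Per-variable AR noise models fitted to historical climate."""
    variables: dict[str, VariableNoise]
    order: int = 1


def _fit_one(values: np.ndarray, order: int) -> VariableNoise:
    mean = float(values.mean())
    centred = values - mean
    if np.allclose(centred, 0.0):
        return VariableNoise(mean, np.zeros(order), 0.0)
    fit = AutoReg(centred, lags=order, trend="n").fit()
    coefs = np.asarray(fit.params, dtype=float)
    # stationarity guard: clamp the coefficient vector if any root of the
    # AR polynomial falls on or inside the unit circle
    roots = np.roots(np.concatenate([[1.0], -coefs]))
    if roots.size and np.max(np.abs(roots)) >= 1.0:
        warnings.warn("non-stationary AR fit; clamping coefficient magnitude")
        coefs = coefs * (0.98 / np.max(np.abs(roots)))
    sd = float(np.sqrt(fit.sigma2))
    return VariableNoise(mean, coefs, sd)


def fit_ar_noise(climate: dict[str, AnnualSeries], order: int = 1) -> ARNoiseModel:
    """Fit mean-removed AR(order) noise models to each historical series."""
    out = {}
    for name, series in climate.items():
        if len(series) < 50:
            raise InputError(f"{name}: need >= 50 years to fit the noise model")
        out[name] = _fit_one(series.values, order)
    return ARNoiseModel(out, order=order)


def _ramp(years: np.ndarray) -> np.ndarray:
    """Linear warming ramp: 0 at RAMP_START rising to WARMING_DEGF at RAMP_END."""
    r = WARMING_DEGF * (years - RAMP_START) / (RAMP_END - RAMP_START)
    return np.clip(r, 0.0, WARMING_DEGF)


def make_climate(climate_id: int, years: np.ndarray, noise_model: ARNoiseModel,
                 seed, noise_on: bool = True,
                 shared_noise: dict[str, np.ndarray] | None = None,
                 ) -> dict[str, AnnualSeries]:
    """Build one future climate on the given year grid.

    Climate 1: long-term mean + AR noise for all three variables.
    Climate 2: same, except tmax and tmin add the linear +4.5 degF ramp
    anchored 2015 -> 2098.  ``shared_noise`` lets paired climates reuse one
    noise draw so their difference is the trend alone.
    """
    if climate_id not in (1, 2):
        raise ConfigurationError(f"unknown climate id {climate_id}")
    years = np.asarray(years, dtype=np.int64)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    units = {"precip": "inches", "tmax": "degF", "tmin": "degF"}
    out = {}
    for name in ("precip", "tmax", "tmin"):
        vn = noise_model.variables[name]
        if noise_on:
            noise = (shared_noise[name] if shared_noise is not None
                     else vn.simulate(years.size, rng))
        else:
            noise = np.zeros(years.size)
        vals = vn.mean + noise
        if climate_id == 2 and name in ("tmax", "tmin"):
            vals = vals + _ramp(years)
        out[name] = AnnualSeries(years, vals, units=units[name], name=name)
    return out


def draw_shared_noise(noise_model: ARNoiseModel, n: int, seed
                      ) -> dict[str, np.ndarray]:
    """One noise path per variable, reusable across paired climates."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return {name: vn.simulate(n, rng)
            for name, vn in noise_model.variables.items()}


def make_grazing_scenario(base_level: str, years: np.ndarray,
                          pulse: bool = False) -> AnnualSeries:
    """Constant grazing pressure at the base level, optionally with the
    10-year +1 pulse starting 2059.  Heavy base + pulse is refused: extra
    pressure is never stacked on an already heavily grazed scenario."""
    if base_level not in GRAZING_LEVELS:
        raise ConfigurationError(f"unknown grazing level {base_level!r}")
    if pulse and base_level == "heavy":
        raise ConfigurationError(
            "grazing pulse not applicable to the heavy-grazing scenarios")
    years = np.asarray(years, dtype=np.int64)
    vals = np.full(years.size, GRAZING_LEVELS[base_level])
    if pulse:
        in_pulse = (years >= PULSE_START) & (years < PULSE_START + PULSE_YEARS)
        vals = vals + PULSE_INCREMENT * in_pulse
    return AnnualSeries(years, vals, units="index", name="grazing")


def make_fire_scenario(tmax: AnnualSeries,
                       threshold: float = FIRE_THRESHOLD_F) -> AnnualSeries:
    """Binary fire series: 1 in years with tmax strictly above threshold."""
    vals = (tmax.values > threshold).astype(float)
    return AnnualSeries(tmax.years, vals, units="binary", name="fire")


@dataclass
class ScenarioBundle:
    """One of the six disturbance futures, fully assembled."""
    scenario_id: int
    climate_id: int
    grazing_level: str
    pulse: bool                   # pulse requested by the scenario design
    pulse_applied: bool           # False when refused (heavy base)
    fire_rule: bool
    climate: dict[str, AnnualSeries]
    grazing: AnnualSeries
    fire: AnnualSeries

    @property
    def years(self) -> np.ndarray:
        return self.grazing.years


# Table of the six scenarios: (climate id, pulse?, fire rule?)
SCENARIO_TABLE = {
    1: (1, False, False),
    2: (1, True, False),
    3: (1, False, True),
    4: (2, False, False),
    5: (2, True, False),
    6: (2, False, True),
}


def assemble_scenarios(noise_model: ARNoiseModel,
                       measured: dict[str, AnnualSeries],
                       base_level: str,
                       seed) -> list[ScenarioBundle]:
    """Build all six scenario bundles over 1998-2098 for one grazing level.

    ``measured`` supplies the 1998-2014 segment of each climate variable
    (a labelled stand-in in the synthetic pipeline); 2015-2098 is simulated.
    Scenarios 1-3 run climate 1, 4-6 climate 2; within a call the two
    climates share one noise draw, so scenario pairs differ only by the
    prescribed trend, pulse or fire rule.  Under a heavy base level the
    pulse scenarios are built without the pulse and flagged.
    """
    for name in ("precip", "tmax", "tmin"):
        m = measured[name]
        if m.start != MEASURED_START or m.end != MEASURED_END:
            raise InputError(
                f"measured segment for {name} must cover "
                f"{MEASURED_START}-{MEASURED_END}")
    future_years = np.arange(RAMP_START, RAMP_END + 1)
    noise = draw_shared_noise(noise_model, future_years.size,
                              derive_seed(seed, "noise"))
    climates = {}
    for cid in (1, 2):
        future = make_climate(cid, future_years, noise_model,
                              derive_seed(seed, "climate", cid),
                              noise_on=True, shared_noise=noise)
        climates[cid] = {name: concat_years(measured[name], future[name])
                         for name in future}
    all_years = climates[1]["precip"].years
    bundles = []
    for sid, (cid, pulse, fire_rule) in SCENARIO_TABLE.items():
        applied = pulse and base_level != "heavy"
        grazing = make_grazing_scenario(base_level, all_years, pulse=applied)
        if fire_rule:
            fire = make_fire_scenario(climates[cid]["tmax"])
        else:
            fire = AnnualSeries(all_years, np.zeros(all_years.size),
                                units="binary", name="fire")
        bundles.append(ScenarioBundle(
            scenario_id=sid, climate_id=cid, grazing_level=base_level,
            pulse=pulse, pulse_applied=applied, fire_rule=fire_rule,
            climate=climates[cid], grazing=grazing, fire=fire))
    return bundles
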