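"""Generator contracts: climate noise structure, driver responses, and the
censored/error-perturbed deposition record."""

import dataclasses

import numpy as np
import pytest

from dunecast import (AnnualSeries, ConfigurationError, DepositionParams,
                      TreeRingParams, WorldConfig, generate_world)
from dunecast.synthetic import (gen_climate, gen_deposition_ages, gen_fire,
                                gen_grazing, gen_tree_ring, mobility_score,
                                true_event_years)
from dunecast.preprocess import build_age_pdf


def lag1_autocorr(x: np.ndarray) -> float:
    x = x - x.mean()
    return float(np.sum(x[1:] * x[:-1]) / np.sum(x * x))


def test_config_validation():
    with pytest.raises(ConfigurationError):
        WorldConfig(years=(1990, 2000))            # shorter than 60 years
    with pytest.raises(ConfigurationError):
        WorldConfig(ar_phi=1.0)
    with pytest.raises(ConfigurationError):
        WorldConfig(grazing_regimes=((1900, 2.0), (1700, 1.0)))
    cfg = WorldConfig()
    cfg.deposition.censor_prob = 1.5
    with pytest.raises(ConfigurationError):
        cfg.__post_init__()


def test_zero_noise_climate_is_constant_at_means():
    cfg = WorldConfig(precip_sd=0.0, tmax_sd=0.0, tmin_sd=0.0)
    cl = gen_climate(cfg)
    assert np.all(cl["precip"].values == cfg.precip_mean)
    assert np.all(cl["tmax"].values == cfg.tmax_mean)
    assert np.all(cl["tmin"].values == cfg.tmin_mean)


@pytest.mark.parametrize("phi,tol", [(0.0, 0.03), (0.6, 0.05)])
def test_climate_lag1_autocorrelation_recovers_phi(phi, tol):
    # oracle: direct sample autocorrelation on a long generated draw
    cfg = WorldConfig(seed=7, years=(1, 10_000), ar_phi=phi)
    cl = gen_climate(cfg)
    assert abs(lag1_autocorr(cl["precip"].values) - phi) < tol


def test_fixed_seed_fixes_every_series_bitwise():
    a = generate_world(WorldConfig(seed=11))
    b = generate_world(WorldConfig(seed=11))
    assert np.array_equal(a.climate["precip"].values, b.climate["precip"].values)
    assert np.array_equal(a.treering.values, b.treering.values)
    assert np.array_equal(a.fire.values, b.fire.values)
    assert a.sites.keys() == b.sites.keys()
    for s in a.sites:
        assert [r.age_year for r in a.sites[s]] == [r.age_year for r in b.sites[s]]


def test_tree_ring_is_the_linear_form_without_noise():
    cfg = WorldConfig(precip_sd=0.0, tmax_sd=0.0, tmin_sd=0.0)
    cl = gen_climate(cfg)
    p = TreeRingParams(noise_sd=0.0)
    idx = gen_tree_ring(cl, p, seed=0)
    expected = (p.intercept + p.precip_coef * cfg.precip_mean
                - p.tmax_coef * cfg.tmax_mean)
    assert np.allclose(idx.values, expected)

    # linearity: +1 inch of rain in one year raises that year by b_p exactly
    bumped = dict(cl)
    v = cl["precip"].values.copy()
    v[100] += 1.0
    bumped["precip"] = cl["precip"].with_values(v)
    idx2 = gen_tree_ring(bumped, p, seed=0)
    delta = idx2.values - idx.values
    assert delta[100] == pytest.approx(p.precip_coef)
    assert np.all(delta[np.arange(delta.size) != 100] == 0)


def test_tree_ring_declines_under_a_warming_trend():
    # noise-free warming ramp forces a strictly decreasing growth index
    cfg = WorldConfig(precip_sd=0.0, tmax_sd=0.0, tmin_sd=0.0)
    cl = gen_climate(cfg)
    ramp = np.linspace(0.0, 5.0, len(cl["tmax"]))
    cl = dict(cl, tmax=cl["tmax"].with_values(cl["tmax"].values + ramp))
    idx = gen_tree_ring(cl, TreeRingParams(noise_sd=0.0), seed=0)
    assert np.all(np.diff(idx.values) < 0)


def test_grazing_and_fire_degenerate_cases():
    cfg = WorldConfig(grazing_regimes=((1590, 1.0),))
    assert np.all(gen_grazing(cfg).values == 1.0)

    cl = gen_climate(cfg)
    quiet = dataclasses.replace(cfg, fire_base_prob=0.0, fire_temp_coeff=0.0)
    assert np.all(gen_fire(quiet, cl["tmax"]).values == 0.0)
    always = dataclasses.replace(cfg, fire_base_prob=1.0, fire_temp_coeff=0.0)
    assert np.all(gen_fire(always, cl["tmax"]).values == 1.0)


def test_fire_binary_and_grazing_nonnegative(default_world):
    assert set(np.unique(default_world.fire.values)) <= {0.0, 1.0}
    assert np.all(default_world.grazing.values >= 0.0)


def _square_wave_mobility(n_events: int, params: DepositionParams) -> AnnualSeries:
    """Mobility series with exactly n_events upward threshold crossings."""
    vals = np.tile([params.threshold - 1.0, params.threshold + 1.0], n_events)
    years = np.arange(1, vals.size + 1)
    return AnnualSeries(years, vals, name="mobility")


def test_deposition_censoring_and_dating_error_degenerate_cases():
    params = DepositionParams(dating_error_sd=0.0, censor_prob=0.0,
                              response_lag=0)
    mob = _square_wave_mobility(50, params)
    recs, truth = gen_deposition_ages(mob, params, "A", site_seed=0)
    assert truth.size == 50
    assert [r.age_year for r in recs] == [float(y) for y in truth]

    gone = DepositionParams(censor_prob=1.0, response_lag=0)
    recs2, _ = gen_deposition_ages(mob, gone, "A", site_seed=0)
    assert recs2 == []


def test_censoring_retention_matches_binomial_oracle():
    # 1,000 true events, p(retain)=0.5: mean retained count over 20 seeds
    # must sit within 3 standard errors of 500
    params = DepositionParams(censor_prob=0.5, dating_error_sd=0.0,
                              response_lag=0)
    mob = _square_wave_mobility(1000, params)
    counts = [len(gen_deposition_ages(mob, params, "A", site_seed=s)[0])
              for s in range(20)]
    se = np.sqrt(1000 * 0.25 / 20)
    assert abs(np.mean(counts) - 500.0) < 3 * se


def test_noise_free_record_puts_pdf_peaks_on_true_event_years():
    # with no censoring and no dating error, the per-site likelihood curve
    # must peak within +/-1 year of each true event
    cfg = WorldConfig(seed=5)
    cfg.deposition.censor_prob = 0.0
    cfg.deposition.dating_error_sd = 0.0
    world = generate_world(cfg)
    assert world.truth_years.size >= 3
    pdf = build_age_pdf(world.sites["A"], cfg.year_grid)
    for y in world.truth_years:
        i = int(y) - cfg.years[0]
        lo, hi = max(i - 1, 0), min(i + 2, pdf.score.size)
        window = pdf.score[lo:hi]
        neighbourhood = pdf.score[max(i - 15, 0):i + 16]
        assert window.max() == pytest.approx(neighbourhood.max())


def test_event_density_matches_design_band(default_world):
    # default mobility calibration aims at ~5-10 events per 400 years
    n = default_world.truth_years.size
    assert 3 <= n <= 15


def test_mobility_event_years_respect_response_lag():
    cfg = WorldConfig(seed=3)
    mob = mobility_score(gen_climate(cfg), gen_grazing(cfg),
                         gen_fire(cfg, gen_climate(cfg)["tmax"]), cfg)
    lag0 = dataclasses.replace(cfg.deposition, response_lag=0)
    lag3 = dataclasses.replace(cfg.deposition, response_lag=3)
    y0 = true_event_years(mob, lag0)
    y3 = true_event_years(mob, lag3)
    kept = y0 + 3 <= mob.end
    assert np.array_equal(y0[kept] + 3, y3)
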