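"""Network engine: delay embedding, partitioning, LM training and its
oracles (finite-difference Jacobian, closed-form least squares)."""

import numpy as np
import pytest

from dunecast import (AnnualSeries, ConfigurationError, InputError,
                      NetworkSpec, SiteData, TrainConfig, embed_delays,
                      partition, train_lm)
from dunecast.ann import (AffineScaler, TrainedNetwork, _flatten, _init_params,
                          loso_crossval, network_jacobian, network_output)
from dunecast.preprocess import DepositionPDF

from conftest import make_series


def series_triplet(n=60, seed=0):
    rng = np.random.default_rng(seed)
    return [make_series(rng.normal(size=n), start=1900) for _ in range(3)]


# --- delay embedding -------------------------------------------------------

def test_delay_row_width_is_inputs_times_lags():
    x, years = embed_delays(series_triplet(), (0, 8))
    assert x.shape[1] == 3 * 9 == 27
    assert years[0] == 1908  # first max_lag years dropped


def test_zero_delay_embedding_is_the_raw_input():
    s = series_triplet()
    x, years = embed_delays(s, (0, 0))
    assert np.array_equal(x, np.column_stack([q.values for q in s]))
    assert np.array_equal(years, s[0].years)


def test_perturbing_one_year_touches_rows_up_to_the_lag_horizon():
    s = series_triplet()
    x0, years = embed_delays(s, (0, 8))
    v = s[0].values.copy()
    t = 30
    v[t] += 1.0
    x1, _ = embed_delays([s[0].with_values(v), s[1], s[2]], (0, 8))
    changed = np.where(np.any(x0 != x1, axis=1))[0]
    changed_years = years[changed]
    year_t = s[0].years[t]
    assert changed_years.min() == year_t
    assert changed_years.max() == year_t + 8


def test_embedding_rejects_short_series():
    with pytest.raises(InputError):
        embed_delays([make_series(np.arange(5.0))], (0, 8))


# --- partitioning ----------------------------------------------------------

def test_partition_counts_follow_rounding_with_remainder_to_training():
    idx = partition(400, (0.5, 0.05, 0.45), seed=0)
    assert (len(idx["train"]), len(idx["val"]), len(idx["test"])) == (200, 20, 180)


def test_partition_is_disjoint_exhaustive_and_reproducible():
    a = partition(97, (0.7, 0.1, 0.2), seed=5)
    b = partition(97, (0.7, 0.1, 0.2), seed=5)
    allidx = np.concatenate([a["train"], a["val"], a["test"]])
    assert np.array_equal(np.sort(allidx), np.arange(97))
    for k in a:
        assert np.array_equal(a[k], b[k])
    c = partition(97, (1.0, 0.0, 0.0), seed=5)
    assert len(c["train"]) == 97


def test_partition_rejects_bad_fractions():
    with pytest.raises(ConfigurationError):
        partition(100, (0.5, 0.5, 0.5), seed=0)


# --- scaling ---------------------------------------------------------------

def test_scaling_round_trip_is_exact_to_1e12(rng):
    x = rng.normal(size=(40, 5)) * 100 + 3
    sc = AffineScaler.fit(x)
    z = sc.transform(x)
    assert z.min() >= -1 - 1e-12 and z.max() <= 1 + 1e-12
    assert np.max(np.abs(sc.inverse(z) - x)) < 1e-12


def test_constant_columns_scale_to_zero():
    x = np.column_stack([np.full(10, 7.0), np.arange(10.0)])
    sc = AffineScaler.fit(x)
    assert np.all(sc.transform(x)[:, 0] == 0.0)


# --- Jacobian oracle -------------------------------------------------------

def test_analytic_jacobian_matches_central_finite_differences(rng):
    # 5-weight toy net: 2 inputs -> 1 tanh neuron -> linear output
    spec = NetworkSpec(n_inputs=2, hidden_layers=(1,))
    w = _flatten(_init_params(spec.layer_sizes,
                              np.random.default_rng(3)))
    assert w.size == 5
    x = rng.normal(size=(7, 2))
    jac = network_jacobian(spec, w, x)
    h = 1e-6
    for j in range(w.size):
        wp, wm = w.copy(), w.copy()
        wp[j] += h
        wm[j] -= h
        fd = (network_output(spec, wp, x) - network_output(spec, wm, x)) / (2 * h)
        denom = np.maximum(np.abs(fd), 1e-8)
        assert np.max(np.abs(jac[:, j] - fd) / denom) < 1e-5


def test_jacobian_matches_finite_differences_on_deep_net(rng):
    spec = NetworkSpec(n_inputs=2, hidden_layers=(3, 2))
    w = _flatten(_init_params(spec.layer_sizes, np.random.default_rng(9)))
    x = rng.normal(size=(5, 2))
    jac = network_jacobian(spec, w, x)
    h = 1e-6
    fd = np.empty_like(jac)
    for j in range(w.size):
        wp, wm = w.copy(), w.copy()
        wp[j] += h
        wm[j] -= h
        fd[:, j] = (network_output(spec, wp, x)
                    - network_output(spec, wm, x)) / (2 * h)
    assert np.max(np.abs(jac - fd)) < 1e-6 * (1 + np.max(np.abs(fd)))


# --- LM training -----------------------------------------------------------

def linear_problem(n=100, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, 3))
    y = x @ np.array([1.5, -2.0, 0.5]) + 3.0
    return x, y


def test_lm_drives_linear_problem_to_machine_precision():
    x, y = linear_problem()
    net = train_lm(NetworkSpec(n_inputs=3), x, y,
                   config=TrainConfig(fractions=(1, 0, 0), max_iterations=50,
                                      seed=1))
    assert net.history["train_mse"][-1] < 1e-10
    assert len(net.history["train_mse"]) <= 50
    # predictions on training rows reproduce the targets
    assert np.max(np.abs(net.predict_matrix(x) - y)) < 1e-5


def test_lm_equals_closed_form_least_squares_on_noisy_rows(rng):
    x = rng.normal(size=(80, 4))
    y = x @ rng.normal(size=4) + 1.0 + rng.normal(0, 0.3, 80)
    cfg = TrainConfig(fractions=(1, 0, 0), max_iterations=200, seed=2)
    net = train_lm(NetworkSpec(n_inputs=4), x, y, config=cfg)
    beta, *_ = np.linalg.lstsq(np.column_stack([x, np.ones(80)]), y, rcond=None)
    ols_pred = np.column_stack([x, np.ones(80)]) @ beta
    assert np.max(np.abs(net.predict_matrix(x) - ols_pred)) < 1e-6


def test_training_mse_non_increasing_over_accepted_steps(rng):
    x = rng.normal(size=(60, 2))
    y = np.tanh(x[:, 0]) - 0.5 * x[:, 1]
    net = train_lm(NetworkSpec(n_inputs=2, hidden_layers=(4,)), x, y,
                   config=TrainConfig(fractions=(1, 0, 0), max_iterations=60,
                                      seed=3))
    mse = np.array(net.history["train_mse"])
    assert np.all(np.diff(mse) <= 1e-15)


def test_masked_rows_never_influence_the_fit(rng):
    x = rng.normal(size=(50, 2))
    y = x @ np.array([1.0, -1.0])
    mask = np.ones(50, dtype=bool)
    mask[::5] = False
    cfg = TrainConfig(fractions=(1, 0, 0), max_iterations=30, seed=4)
    net_a = train_lm(NetworkSpec(n_inputs=2), x, y, mask, cfg)
    y_perturbed = y.copy()
    y_perturbed[~mask] = 1e6  # garbage on masked rows only
    net_b = train_lm(NetworkSpec(n_inputs=2), x, y_perturbed, mask, cfg)
    for (wa, ba), (wb, bb) in zip(net_a.params, net_b.params):
        assert np.array_equal(wa, wb) and np.array_equal(ba, bb)


def test_nan_inputs_rejected():
    x = np.ones((30, 2))
    x[3, 1] = np.nan
    with pytest.raises(InputError):
        train_lm(NetworkSpec(n_inputs=2), x, np.ones(30))


def test_zero_weight_network_outputs_the_descaled_bias(rng):
    x = rng.normal(size=(20, 2))
    y = rng.normal(size=20)
    net = train_lm(NetworkSpec(n_inputs=2), x, y,
                   config=TrainConfig(fractions=(1, 0, 0), max_iterations=1,
                                      seed=0))
    w, b = net.params[0]
    net.params[0] = (np.zeros_like(w), b)
    out = net.predict_matrix(x)
    expected = net.y_scaler.inverse(np.full((1, 1), b[0]))[0, 0]
    assert np.allclose(out, expected)


def test_prediction_is_deterministic(rng):
    x = rng.normal(size=(40, 2))
    y = np.sin(x[:, 0])
    cfg = TrainConfig(fractions=(0.8, 0.1, 0.1), max_iterations=40, seed=9)
    net1 = train_lm(NetworkSpec(n_inputs=2, hidden_layers=(5,)), x, y, config=cfg)
    net2 = train_lm(NetworkSpec(n_inputs=2, hidden_layers=(5,)), x, y, config=cfg)
    assert np.array_equal(net1.predict_matrix(x), net2.predict_matrix(x))


def test_trained_network_json_round_trip(rng):
    x = rng.normal(size=(30, 2))
    y = x[:, 0] - x[:, 1]
    net = train_lm(NetworkSpec(n_inputs=2, hidden_layers=(3,)), x, y,
                   config=TrainConfig(fractions=(1, 0, 0), max_iterations=20,
                                      seed=5))
    clone = TrainedNetwork.from_json(net.to_json())
    assert np.array_equal(clone.predict_matrix(x), net.predict_matrix(x))


# --- leave-one-site-out ----------------------------------------------------

def _toy_site(name, seed=0):
    """Small site whose target is a smooth function of its two inputs."""
    rng = np.random.default_rng(seed)
    n = 120
    years = np.arange(1900, 1900 + n)
    a = np.sin(np.arange(n) / 8.0)
    b = rng.normal(0, 0.05, n)
    inputs = [AnnualSeries(years, a), AnnualSeries(years, b)]
    target = np.clip(np.sin(np.arange(n) / 8.0 - 0.4), 0, None)
    pdf = DepositionPDF(name, years, target, np.ones(n, dtype=bool))
    return SiteData(name, inputs, pdf)


def test_loso_returns_one_result_per_site_and_matches_duplicated_sites():
    sites = [_toy_site("A"), _toy_site("B")]  # identical dynamics
    spec = NetworkSpec(n_inputs=2, hidden_layers=(6,), delay_range=(0, 2))
    cfg = TrainConfig(fractions=(0.8, 0.1, 0.1), max_iterations=60, seed=2)
    res = loso_crossval(sites, spec, cfg, n_repeats=2)
    assert len(res) == 2
    for r in res:
        assert r["score"].penalty_count == 0  # every peak matched in window


def test_loso_needs_at_least_two_sites():
    with pytest.raises(InputError):
        loso_crossval([_toy_site("A")], NetworkSpec(n_inputs=2),
                      TrainConfig(seed=0))
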