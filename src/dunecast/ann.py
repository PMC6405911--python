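"""Dense feedforward networks with input delay lines, trained by
Levenberg-Marquardt (LM).

This is the computational core shared by the two networks in the pipeline:

* the deposition network — a time-delay net (lags 0-8 on every input) with
  hidden layers [3, 30, 30, 3] mapping smoothed tree-ring growth, grazing
  pressure and wildfire occurrence to the deposition-event-score curve;
* the tree-ring network — a single 9-neuron hidden layer mapping
  growing-season precipitation and max/min temperature to the tree-ring
  growth index.

Training is damped Gauss-Newton on the network Jacobian:
``dw = (J'J + mu*I)^-1 J'e`` over the training rows only, with mu scaled
up on rejected steps and down on accepted ones, random year-wise
train/validation/test partitioning, and early stopping on consecutive
validation-MSE increases.  Inputs and targets are affinely scaled to
[-1, 1] internally; hidden activations are tanh, the output is linear.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .rngutil import derive_seed
from .series import AnnualSeries, ConfigurationError, InputError, require_same_grid


@dataclass
class NetworkSpec:
    """Architecture: raw input count, hidden sizes, and the input delay range.

    ``delay_range = (min_lag, max_lag)`` feeds each input variable at lags
    min_lag..max_lag inclusive, so the embedded row width is
    ``n_inputs * (max_lag - min_lag + 1)``.
    """
    n_inputs: int
    hidden_layers: tuple[int, ...] = ()
    delay_range: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        self.hidden_layers = tuple(int(h) for h in self.hidden_layers)
        if self.n_inputs < 1 or any(h < 1 for h in self.hidden_layers):
            raise ConfigurationError("all layer sizes must be >= 1")
        lo, hi = self.delay_range
        if not (0 <= lo <= hi):
            raise ConfigurationError("delay_range must satisfy 0 <= min <= max")

    @property
    def n_lags(self) -> int:
        return self.delay_range[1] - self.delay_range[0] + 1

    @property
    def embedded_width(self) -> int:
        return self.n_inputs * self.n_lags

    @property
    def layer_sizes(self) -> list[int]:
        return [self.embedded_width, *self.hidden_layers, 1]


def deposition_network_spec() -> NetworkSpec:
    """Default deposition net: 3 inputs x lags 0-8, hidden [3, 30, 30, 3]."""
    return NetworkSpec(n_inputs=3, hidden_layers=(3, 30, 30, 3), delay_range=(0, 8))


def treering_network_spec() -> NetworkSpec:
    """Default tree-ring net: 3 climate inputs, one 9-neuron hidden layer."""
    return NetworkSpec(n_inputs=3, hidden_layers=(9,), delay_range=(0, 0))


@dataclass
class TrainConfig:
    """LM training hyper-parameters.

    fractions are the train/validation/test shares of the (masked) rows;
    mu is the LM damping parameter, multiplied by ``mu_inc`` when a step
    fails to reduce the training SSE and divided by ``mu_dec`` when it
    succeeds.  Training stops at ``max_iterations`` accepted steps, when
    mu exceeds ``mu_max``, or after ``patience`` consecutive iterations
    without a validation-MSE improvement; the returned weights are the
    best-validation ones.
    """
    fractions: tuple[float, float, float] = (0.9, 0.05, 0.05)
    max_iterations: int = 300
    mu0: float = 1e-3
    mu_inc: float = 10.0
    mu_dec: float = 10.0
    mu_max: float = 1e10
    patience: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        f = self.fractions
        if any(x < 0 or x > 1 for x in f) or abs(sum(f) - 1.0) > 1e-9:
            raise ConfigurationError("partition fractions must lie in [0,1] and sum to 1")
        if self.max_iterations < 1:
            raise ConfigurationError("max_iterations must be >= 1")


# --- affine [-1, 1] scaling ------------------------------------------------

@dataclass
class AffineScaler:
    """Per-column min-max map onto [-1, 1]; constant columns map to 0."""
    lo: np.ndarray
    hi: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray) -> "AffineScaler":
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return cls(lo=x.min(axis=0), hi=x.max(axis=0))

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        span = self.hi - self.lo
        safe = np.where(span > 0, span, 1.0)
        out = 2.0 * (x - self.lo) / safe - 1.0
        return np.where(span > 0, out, 0.0)

    def inverse(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        span = self.hi - self.lo
        return (z + 1.0) / 2.0 * span + self.lo


# --- delay embedding and partitioning --------------------------------------

def embed_delays(inputs: list[AnnualSeries],
                 delay_range: tuple[int, int] = (0, 0),
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Time-delay design matrix from k aligned annual series.

    Row for year t holds every input at lags min_lag..max_lag (grouped by
    variable, lag-major within a variable); the first max_lag years of the
    grid are dropped.  Returns ``(X, years)`` with X of width
    ``k * (max_lag - min_lag + 1)``.  Sites are embedded by separate calls,
    so no row ever mixes years across site boundaries.
    """
    years = require_same_grid(*inputs)
    lo, hi = delay_range
    n = years.size
    if n <= hi:
        raise InputError(f"series length {n} must exceed max_lag {hi}")
    rows = n - hi
    cols = []
    for s in inputs:
        for lag in range(lo, hi + 1):
            cols.append(s.values[hi - lag: n - lag])
    x = np.column_stack(cols)
    assert x.shape == (rows, len(inputs) * (hi - lo + 1))
    return x, years[hi:]


def partition(n: int, fractions: tuple[float, float, float],
              seed) -> dict[str, np.ndarray]:
    """Random disjoint exhaustive train/val/test split of n row indices.

    Validation and test counts are ``round(fraction * n)``; the remainder
    goes to training.  Reproducible under the given seed.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError("fractions must sum to 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_val = int(round(fractions[1] * n))
    n_test = int(round(fractions[2] * n))
    n_train = n - n_val - n_test
    if n_train < 0:
        raise ConfigurationError("rounded val+test counts exceed n")
    perm = rng.permutation(n)
    return {
        "train": np.sort(perm[:n_train]),
        "val": np.sort(perm[n_train:n_train + n_val]),
        "test": np.sort(perm[n_train + n_val:]),
    }


# --- network forward pass and Jacobian -------------------------------------

def _init_params(layer_sizes: list[int], rng: np.random.Generator
                 ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded uniform init in [-0.5, 0.5] scaled by 1/sqrt(fan_in)."""
    params = []
    for d_in, d_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        scale = 1.0 / np.sqrt(d_in)
        w = rng.uniform(-0.5, 0.5, size=(d_out, d_in)) * scale
        b = rng.uniform(-0.5, 0.5, size=d_out) * scale
        params.append((w, b))
    return params


def _flatten(params) -> np.ndarray:
    return np.concatenate([np.concatenate([w.ravel(), b]) for w, b in params])


def _unflatten(vec: np.ndarray, layer_sizes: list[int]):
    params = []
    i = 0
    for d_in, d_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        w = vec[i:i + d_out * d_in].reshape(d_out, d_in)
        i += d_out * d_in
        b = vec[i:i + d_out]
        i += d_out
        params.append((w, b))
    return params


def _forward(params, x: np.ndarray) -> list[np.ndarray]:
    """Activations per layer; tanh hidden, linear scalar output."""
    acts = [x]
    a = x
    for li, (w, b) in enumerate(params):
        z = a @ w.T + b
        a = z if li == len(params) - 1 else np.tanh(z)
        acts.append(a)
    return acts


def _jacobian(params, acts: list[np.ndarray]) -> np.ndarray:
    """d(output)/d(weights) for a scalar-output net, one row per sample.

    Backpropagates sensitivities D_l = d y / d z_l and assembles
    d y / d W_l[i, j] = D_l[:, i] * a_{l-1}[:, j] into an (n, p) matrix in
    the same order as :func:`_flatten`.
    """
    n = acts[0].shape[0]
    L = len(params)
    deltas = [None] * L
    deltas[L - 1] = np.ones((n, 1))
    for li in range(L - 2, -1, -1):
        w_next = params[li + 1][0]
        deltas[li] = (deltas[li + 1] @ w_next) * (1.0 - acts[li + 1] ** 2)
    blocks = []
    for li in range(L):
        d = deltas[li]                      # (n, d_out)
        a_prev = acts[li]                   # (n, d_in)
        jw = np.einsum("ni,nj->nij", d, a_prev).reshape(n, -1)
        blocks.append(jw)
        blocks.append(d)
    return np.concatenate(blocks, axis=1)


@dataclass
class TrainedNetwork:
    """Fitted weights plus the scaling needed to predict in target units."""
    spec: NetworkSpec
    params: list
    x_scaler: AffineScaler
    y_scaler: AffineScaler
    history: dict = field(default_factory=dict)

    def predict_matrix(self, x: np.ndarray) -> np.ndarray:
        """Predict from an embedded design matrix; returns de-scaled values."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.spec.embedded_width:
            raise InputError(
                f"input width {x.shape[1]} != trained width {self.spec.embedded_width}")
        z = self.x_scaler.transform(x)
        out = _forward(self.params, z)[-1][:, 0]
        return self.y_scaler.inverse(out[:, None])[:, 0]

    def predict_series(self, inputs: list[AnnualSeries]) -> AnnualSeries:
        """Embed aligned input series with the trained delay line and predict."""
        x, years = embed_delays(inputs, self.spec.delay_range)
        return AnnualSeries(years, self.predict_matrix(x), name="prediction")

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "spec": {"n_inputs": self.spec.n_inputs,
                     "hidden_layers": list(self.spec.hidden_layers),
                     "delay_range": list(self.spec.delay_range)},
            "params": [[w.tolist(), b.tolist()] for w, b in self.params],
            "x_scaler": {"lo": self.x_scaler.lo.tolist(),
                         "hi": self.x_scaler.hi.tolist()},
            "y_scaler": {"lo": self.y_scaler.lo.tolist(),
                         "hi": self.y_scaler.hi.tolist()},
            "history": {k: v for k, v in self.history.items()
                        if k != "partition"},
        }
        text = json.dumps(doc)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "TrainedNetwork":
        raw = str(text_or_path)
        text = raw if raw.lstrip().startswith("{") else Path(raw).read_text()
        doc = json.loads(text)
        spec = NetworkSpec(doc["spec"]["n_inputs"],
                           tuple(doc["spec"]["hidden_layers"]),
                           tuple(doc["spec"]["delay_range"]))
        params = [(np.asarray(w), np.asarray(b)) for w, b in doc["params"]]
        return cls(spec, params,
                   AffineScaler(np.asarray(doc["x_scaler"]["lo"]),
                                np.asarray(doc["x_scaler"]["hi"])),
                   AffineScaler(np.asarray(doc["y_scaler"]["lo"]),
                                np.asarray(doc["y_scaler"]["hi"])),
                   doc.get("history", {}))


def _sse(params, x, y) -> float:
    pred = _forward(params, x)[-1][:, 0]
    r = y - pred
    return float(r @ r)


def train_lm(spec: NetworkSpec, x: np.ndarray, y: np.ndarray,
             mask: np.ndarray | None = None,
             config: TrainConfig | None = None) -> TrainedNetwork:
    """Fit the network to (x, y) rows by Levenberg-Marquardt.

    ``x`` is an already-embedded design matrix of width
    ``spec.embedded_width``; ``mask`` (if given) removes rows from every
    error and Jacobian term before partitioning — masked years never touch
    the fit.  Returns the weights with the best validation MSE (or final
    weights when the validation share is zero).
    """
    config = config or TrainConfig()
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if x.shape[0] != y.size:
        raise InputError("x and y row counts differ")
    if x.shape[1] != spec.embedded_width:
        raise InputError(
            f"design width {x.shape[1]} != spec embedded width {spec.embedded_width}")
    if np.any(~np.isfinite(x)):
        raise InputError("NaN/inf in inputs")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        x, y = x[mask], y[mask]
    if np.any(~np.isfinite(y)):
        raise InputError("NaN/inf in unmasked targets")
    n = x.shape[0]
    if n < 3:
        raise InputError("too few rows to train")

    x_scaler = AffineScaler.fit(x)
    y_scaler = AffineScaler.fit(y[:, None])
    xs = x_scaler.transform(x)
    ys = y_scaler.transform(y[:, None])[:, 0]

    idx = partition(n, config.fractions, (config.seed, 1))
    it_, iv = idx["train"], idx["val"]
    if it_.size == 0:
        raise InputError("empty training partition")
    xt, yt = xs[it_], ys[it_]
    xv, yv = xs[iv], ys[iv]

    layer_sizes = spec.layer_sizes
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 2)))
    params = _init_params(layer_sizes, rng)
    w = _flatten(params)
    p = w.size
    mu = config.mu0

    sse = _sse(params, xt, yt)
    best_w = w.copy()
    best_val = np.inf
    prev_val = np.inf
    fails = 0
    hist_train, hist_val = [], []
    stop_reason = "max_iterations"

    for _ in range(config.max_iterations):
        acts = _forward(params, xt)
        e = yt - acts[-1][:, 0]
        jac = _jacobian(params, acts)
        jtj = jac.T @ jac
        jte = jac.T @ e
        accepted = False
        while mu <= config.mu_max:
            try:
                dw = np.linalg.solve(jtj + mu * np.eye(p), jte)
            except np.linalg.LinAlgError:
                mu *= config.mu_inc
                continue
            cand = _unflatten(w + dw, layer_sizes)
            cand_sse = _sse(cand, xt, yt)
            if cand_sse < sse:
                w = w + dw
                params = cand
                sse = cand_sse
                mu = max(mu / config.mu_dec, 1e-20)
                accepted = True
                break
            mu *= config.mu_inc
        if not accepted:
            stop_reason = "mu_overflow"
            break
        hist_train.append(sse / max(xt.shape[0], 1))
        if iv.size > 0:
            val = _sse(params, xv, yv) / iv.size
            hist_val.append(val)
            if val < best_val:
                best_val = val
                best_w = w.copy()
            if val >= prev_val:
                fails += 1
                if fails >= config.patience:
                    stop_reason = "validation"
                    break
            else:
                fails = 0
            prev_val = val
        else:
            best_w = w.copy()

    final = _unflatten(best_w, layer_sizes)
    history = {
        "train_mse": hist_train,
        "val_mse": hist_val,
        "stop_reason": stop_reason,
        "n_rows": int(n),
        "partition": {k: v.tolist() for k, v in idx.items()},
        "seed": config.seed,
    }
    return TrainedNetwork(spec, final, x_scaler, y_scaler, history)


def network_jacobian(spec: NetworkSpec, flat_weights: np.ndarray,
                     x: np.ndarray) -> np.ndarray:
    """Analytic d(output)/d(weights) at given weights — exposed for testing
    against finite differences."""
    params = _unflatten(np.asarray(flat_weights, dtype=float), spec.layer_sizes)
    acts = _forward(params, np.atleast_2d(x))
    return _jacobian(params, acts)


def network_output(spec: NetworkSpec, flat_weights: np.ndarray,
                   x: np.ndarray) -> np.ndarray:
    """Scaled-space network output at given flat weights (testing hook)."""
    params = _unflatten(np.asarray(flat_weights, dtype=float), spec.layer_sizes)
    return _forward(params, np.atleast_2d(x))[-1][:, 0]


# --- leave-one-site-out cross-validation -----------------------------------

@dataclass
class SiteData:
    """One site's aligned input series and masked training target."""
    name: str
    inputs: list
    target: object  # DepositionPDF

    def design(self, delay_range) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        x, years = embed_delays(self.inputs, delay_range)
        off = years[0] - self.target.years[0]
        y = self.target.score[off: off + years.size]
        m = self.target.train_mask[off: off + years.size]
        return x, y, m, years


def train_best_of(spec: NetworkSpec, sites: list[SiteData],
                  config: TrainConfig, n_repeats: int = 1,
                  detect_params=None, default_window: int = 13,
                  seed_label="best-of") -> "TrainedNetwork":
    """Train ``n_repeats`` networks on the stacked sites and keep the one
    whose in-sample predictions best reproduce the sites' target peaks.

    Selection uses the peak-location score (not MSE), matching how ensemble
    repeats are ranked elsewhere; only the training sites are scored, so
    selection never sees held-out data.  Ties break toward the earlier
    repeat.
    """
    from . import selection

    detect_params = detect_params or selection.PeakDetectParams()
    xs, ys, ms, designs = [], [], [], []
    targets = {}
    for s in sites:
        x, y, m, years = s.design(spec.delay_range)
        xs.append(x)
        ys.append(y)
        ms.append(m)
        designs.append((s.name, x, years))
        # peaks are compared over the years the net can actually predict:
        # the delay line drops the first max_lag years of the grid
        targ = s.target.as_series().window(int(years[0]), int(years[-1]))
        targets[s.name] = selection.detect_peaks(targ, detect_params,
                                                 site=s.name)
    window = max(selection.global_peak_window(targets, default_window), 1)
    x_all, y_all, m_all = np.vstack(xs), np.concatenate(ys), np.concatenate(ms)
    best_net, best_key = None, None
    for r in range(n_repeats):
        cfg = TrainConfig(fractions=config.fractions,
                          max_iterations=config.max_iterations,
                          mu0=config.mu0, mu_inc=config.mu_inc,
                          mu_dec=config.mu_dec, mu_max=config.mu_max,
                          patience=config.patience,
                          seed=derive_seed(config.seed, seed_label, r))
        net = train_lm(spec, x_all, y_all, m_all, cfg)
        pred_peaks = {
            name: selection.detect_peaks(
                AnnualSeries(years, net.predict_matrix(x)),
                detect_params, site=name)
            for name, x, years in designs}
        score = selection.score_repeat(pred_peaks, targets, window,
                                       repeat_id=r)
        key = (score.total, r)
        if best_key is None or key < best_key:
            best_net, best_key = net, key
    best_net.history["selection_score"] = best_key[0]
    return best_net


def loso_crossval(sites: list[SiteData], spec: NetworkSpec,
                  config: TrainConfig, detect_params=None,
                  default_window: int = 13, n_repeats: int = 1) -> list[dict]:
    """Leave-one-site-out: train on all other sites, predict the held-out one.

    With ``n_repeats > 1``, each fold trains several networks and keeps the
    one that best reproduces the *training* sites' peaks.  Returns one dict
    per site with the out-of-sample prediction, the detected peak sets, the
    peak window and the peak-location score.  A high score (>= penalty)
    flags a site whose conditions the remaining sites do not cover; it is
    reported, not raised.
    """
    from . import selection

    if len(sites) < 2:
        raise InputError("leave-one-site-out needs >= 2 sites")
    detect_params = detect_params or selection.PeakDetectParams()
    results = []
    for k, held in enumerate(sites):
        train_sites = [s for j, s in enumerate(sites) if j != k]
        net = train_best_of(spec, train_sites, config, n_repeats=n_repeats,
                            detect_params=detect_params,
                            default_window=default_window,
                            seed_label=("loso", k))
        pred = net.predict_series(held.inputs)
        target_series = held.target.as_series().window(pred.start, pred.end)
        target_peaks = selection.detect_peaks(target_series, detect_params,
                                              site=held.name)
        pred_peaks = selection.detect_peaks(pred, detect_params, site=held.name)
        window = selection.peak_window(target_peaks, default_window=default_window)
        score = selection.score_repeat({held.name: pred_peaks},
                                       {held.name: target_peaks}, window)
        results.append({
            "site": held.name,
            "prediction": pred,
            "network": net,
            "target_peaks": target_peaks,
            "predicted_peaks": pred_peaks,
            "window": window,
            "score": score,
        })
    return results
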