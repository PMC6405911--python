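"""End-to-end orchestration of the two-network forecasting analysis.

The full run is: generate (or load) the world's annual records and dated
deposition events -> smooth inputs and build masked per-site targets ->
stage 1 cross-validation of the deposition network -> stage 2 tree-ring
futures (tree-ring network, repeat ensemble, extreme-value screen) ->
stage 3 deposition forecasts for the six disturbance scenarios at three
grazing levels (deposition network ensemble, peak-location screening, top
10% mean +/- SE).  Everything is a pure function of the run configuration,
including its master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from . import ann, preprocess, scenarios, selection
from .rngutil import derive_seed
from .series import AnnualSeries, InputError, concat_years
from .synthetic import World, WorldConfig, generate_world, write_world

log = logging.getLogger("dunecast")

ANN2_TRAIN_START = 1908   # instrumental-era window used to fit the tree-ring net

TREERING_SPAN = 0.2       # RLOESS span for the tree-ring / climate inputs
GRAZING_MA_FACTOR = 0.1   # moving-average window fraction for grazing


@dataclass
class RunConfig:
    """Configuration of one full pipeline run.

    Desk-scale defaults keep a laptop run tractable (200 deposition-net
    repeats, 500 tree-ring-net repeats, LM capped at 120 iterations);
    ``full=True`` restores the 5,000 / 8,000 repeat ensembles and the
    300-iteration cap.
    """
    seed: int = 0
    world: WorldConfig = field(default_factory=WorldConfig)
    ann1_repeats: int = 200
    ann2_repeats: int = 500
    crossval_repeats: int = 3
    max_iterations: int = 120
    full: bool = False
    # partition fractions
    ann1_crossval_fractions: tuple = (0.9, 0.05, 0.05)
    ann1_scenario_fractions: tuple = (0.5, 0.05, 0.45)
    ann2_fractions: tuple = (0.7, 0.1, 0.2)
    # preprocessing
    gap_years: int = 20
    eps_fraction: float = 1e-6
    # peak scoring
    detect: selection.PeakDetectParams = field(
        default_factory=selection.PeakDetectParams)
    default_window: int = selection.DEFAULT_WINDOW
    top_fraction: float = selection.TOP_FRACTION

    def __post_init__(self) -> None:
        if self.full:
            self.ann1_repeats = 5000
            self.ann2_repeats = 8000
            self.max_iterations = 300
        if self.ann1_repeats < 1 or self.ann2_repeats < 1:
            raise ValueError("repeat counts must be >= 1")

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg.config_hash()} seed={cfg.seed}\n")
        df.to_csv(fh, index=False)


# --- shared preprocessing --------------------------------------------------

def historical_ann1_inputs(world: World) -> list[AnnualSeries]:
    """Smoothed deposition-network inputs on the historical grid:
    RLOESS(0.2) tree-ring index, moving-average(0.1) grazing, raw fire."""
    treering = preprocess.rloess_smooth(world.treering, TREERING_SPAN)
    grazing = preprocess.moving_average(world.grazing, GRAZING_MA_FACTOR)
    return [treering, grazing, world.fire]


def build_sites(world: World, cfg: RunConfig) -> list[ann.SiteData]:
    """Per-site paired inputs and masked deposition targets."""
    inputs = historical_ann1_inputs(world)
    targets = preprocess.site_targets(world.sites, world.config.year_grid,
                                      gap_years=cfg.gap_years,
                                      eps_fraction=cfg.eps_fraction)
    return [ann.SiteData(name, inputs, targets[name]) for name in targets]


def _stack_sites(sites: list[ann.SiteData], delay_range
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    xs, ys, ms = [], [], []
    for s in sites:
        x, y, m, _ = s.design(delay_range)
        xs.append(x)
        ys.append(y)
        ms.append(m)
    return np.vstack(xs), np.concatenate(ys), np.concatenate(ms)


# --- stage: tree-ring futures ----------------------------------------------

@dataclass
class TreeRingFutures:
    """Screened ensemble summary of simulated tree-ring growth, per climate."""
    mean: dict[int, AnnualSeries]
    se: dict[int, AnnualSeries]
    n_repeats: int
    n_kept: dict[int, int]
    holdout_r2: float           # mean test-partition R^2 across repeats
    climates: dict[int, dict[str, AnnualSeries]]
    noise_model: scenarios.ARNoiseModel
    measured: dict[str, AnnualSeries]


def run_ann2_stage(cfg: RunConfig, world: World,
                   outdir: Path | None = None) -> TreeRingFutures:
    """Ensemble of tree-ring nets: train on the instrumental-era window,
    simulate 1998-2098 growth under climates 1 and 2, screen extreme
    repeats, summarise mean +/- SE."""
    y0 = max(ANN2_TRAIN_START, world.config.years[0])
    y1 = world.config.years[1]
    hist = {name: s.window(y0, y1) for name, s in world.climate.items()}
    smooth_hist = [preprocess.rloess_smooth(hist[n], TREERING_SPAN)
                   for n in ("precip", "tmax", "tmin")]
    # target smoothed with the same span as the inputs: the smoother is
    # (near-)linear, so the climate->growth relation is preserved and the
    # net is not asked to reproduce frequencies its inputs no longer carry
    target = preprocess.rloess_smooth(world.treering.window(y0, y1),
                                      TREERING_SPAN)

    spec = ann.treering_network_spec()
    x_hist, _ = ann.embed_delays(smooth_hist, spec.delay_range)
    y_hist = target.values

    noise_model = scenarios.fit_ar_noise(hist)
    measured_years = np.arange(scenarios.MEASURED_START,
                               scenarios.MEASURED_END + 1)
    # labelled synthetic stand-in for the instrumental 1998-2014 segment
    measured = scenarios.make_climate(1, measured_years, noise_model,
                                      derive_seed(cfg.seed, "measured"))
    noise = scenarios.draw_shared_noise(
        noise_model, scenarios.RAMP_END - scenarios.RAMP_START + 1,
        derive_seed(cfg.seed, "future-noise"))
    future_years = np.arange(scenarios.RAMP_START, scenarios.RAMP_END + 1)
    climates = {}
    x_future = {}
    for cid in (1, 2):
        future = scenarios.make_climate(cid, future_years, noise_model,
                                        derive_seed(cfg.seed, "climate", cid),
                                        shared_noise=noise)
        full = {n: concat_years(measured[n], future[n]) for n in future}
        climates[cid] = full
        smooth_future = [preprocess.rloess_smooth(full[n], TREERING_SPAN)
                         for n in ("precip", "tmax", "tmin")]
        x_future[cid], fut_years = ann.embed_delays(smooth_future,
                                                    spec.delay_range)

    repeats: dict[int, list[np.ndarray]] = {1: [], 2: []}
    r2s: list[float] = []
    for r in range(cfg.ann2_repeats):
        tcfg = ann.TrainConfig(fractions=cfg.ann2_fractions,
                               max_iterations=cfg.max_iterations,
                               seed=derive_seed(cfg.seed, "ann2", r))
        net = ann.train_lm(spec, x_hist, y_hist, config=tcfg)
        for cid in (1, 2):
            repeats[cid].append(net.predict_matrix(x_future[cid]))
        itest = net.history["partition"]["test"]
        if itest:
            yt = y_hist[itest]
            pred = net.predict_matrix(x_hist[itest])
            ss_res = float(np.sum((yt - pred) ** 2))
            ss_tot = float(np.sum((yt - yt.mean()) ** 2))
            if ss_tot > 0:
                r2s.append(1.0 - ss_res / ss_tot)

    mean, se, n_kept = {}, {}, {}
    for cid in (1, 2):
        keep = selection.screen_extreme(repeats[cid])
        if not keep:
            raise InputError("all tree-ring repeats screened out as extreme")
        n_kept[cid] = len(keep)
        curves = [AnnualSeries(fut_years, repeats[cid][i], units="index",
                               name=f"treering_c{cid}") for i in keep]
        if len(curves) >= 2:
            mean[cid], se[cid] = selection.summarize(curves)
        else:
            mean[cid] = curves[0]
            se[cid] = curves[0].with_values(np.zeros(len(curves[0])))
    log.info("tree-ring stage: %d repeats, kept %s", cfg.ann2_repeats, n_kept)

    holdout_r2 = float(np.mean(r2s)) if r2s else float("nan")
    result = TreeRingFutures(mean, se, cfg.ann2_repeats, n_kept, holdout_r2,
                             climates, noise_model, measured)
    if outdir is not None:
        df = pd.DataFrame({
            "year": fut_years,
            "mean_climate1": mean[1].values, "se_climate1": se[1].values,
            "mean_climate2": mean[2].values, "se_climate2": se[2].values,
        })
        _write_csv(df, Path(outdir) / "treering_futures.csv", cfg)
    return result


# --- stage: deposition forecasts -------------------------------------------

def scenario_ann1_inputs(world: World, bundle: scenarios.ScenarioBundle,
                         futures: TreeRingFutures) -> list[AnnualSeries]:
    """Deposition-net inputs over the forecast window, with the historical
    tail prepended so the delay line can emit predictions from 1998 on."""
    hist_tree, hist_graze, hist_fire = historical_ann1_inputs(world)
    max_lag = ann.deposition_network_spec().delay_range[1]
    tail0 = world.config.years[1] - max_lag + 1
    tree = concat_years(hist_tree.window(tail0, world.config.years[1]),
                        futures.mean[bundle.climate_id])
    graze = concat_years(
        hist_graze.window(tail0, world.config.years[1]),
        preprocess.moving_average(bundle.grazing, GRAZING_MA_FACTOR))
    fire = concat_years(hist_fire.window(tail0, world.config.years[1]),
                        bundle.fire)
    return [tree, graze, fire]


@dataclass
class DepositionForecasts:
    """Top-fraction ensemble summaries per (grazing level, scenario id)."""
    mean: dict[tuple[str, int], AnnualSeries]
    se: dict[tuple[str, int], AnnualSeries]
    scores: list[selection.RepeatScore]
    selected_ids: list[int]
    window: int
    bundles: dict[str, list[scenarios.ScenarioBundle]]


def run_ann1_stage(cfg: RunConfig, world: World, futures: TreeRingFutures,
                   outdir: Path | None = None) -> DepositionForecasts:
    """Deposition-network ensemble over the six scenarios x three grazing
    levels, screened by peak-location score against the training targets."""
    sites = build_sites(world, cfg)
    spec = ann.deposition_network_spec()
    x_all, y_all, m_all = _stack_sites(sites, spec.delay_range)

    # targets restricted to the years the delay line lets the net predict
    site_design = {s.name: s.design(spec.delay_range) for s in sites}
    target_peaks = {}
    for s in sites:
        years = site_design[s.name][3]
        targ = s.target.as_series().window(int(years[0]), int(years[-1]))
        target_peaks[s.name] = selection.detect_peaks(targ, cfg.detect,
                                                      site=s.name)
    window = selection.global_peak_window(target_peaks, cfg.default_window)

    bundles = {lvl: scenarios.assemble_scenarios(
        futures.noise_model, futures.measured, lvl,
        derive_seed(cfg.seed, "scenarios", lvl))
        for lvl in scenarios.GRAZING_LEVELS}
    scenario_inputs = {
        (lvl, b.scenario_id): scenario_ann1_inputs(world, b, futures)
        for lvl, bs in bundles.items() for b in bs}

    scores: list[selection.RepeatScore] = []
    forecast_store: dict[tuple[str, int], list[AnnualSeries]] = {
        key: [] for key in scenario_inputs}
    for r in range(cfg.ann1_repeats):
        tcfg = ann.TrainConfig(fractions=cfg.ann1_scenario_fractions,
                               max_iterations=cfg.max_iterations,
                               seed=derive_seed(cfg.seed, "ann1", r))
        net = ann.train_lm(spec, x_all, y_all, m_all, tcfg)
        pred_peaks = {}
        for s in sites:
            x, _, _, years = site_design[s.name]
            curve = AnnualSeries(years, net.predict_matrix(x))
            pred_peaks[s.name] = selection.detect_peaks(curve, cfg.detect,
                                                        site=s.name)
        score = selection.score_repeat(pred_peaks, target_peaks, window,
                                       repeat_id=r)
        scores.append(score)
        for key, inputs in scenario_inputs.items():
            forecast_store[key].append(net.predict_series(inputs))
        if (r + 1) % 25 == 0:
            log.info("deposition stage: repeat %d/%d", r + 1, cfg.ann1_repeats)

    selected = selection.select_top(scores, cfg.top_fraction)
    sel_ids = [s.repeat_id for s in selected]
    mean, se = {}, {}
    for key, curves in forecast_store.items():
        chosen = [curves[i] for i in sel_ids]
        if len(chosen) >= 2:
            mean[key], se[key] = selection.summarize(chosen)
        else:
            mean[key] = chosen[0]
            se[key] = chosen[0].with_values(np.zeros(len(chosen[0])))

    result = DepositionForecasts(mean, se, scores, sel_ids, window, bundles)
    if outdir is not None:
        _write_csv(pd.DataFrame(
            [(s.repeat_id, s.diff_sum, s.penalty_count, s.total,
              derive_seed(cfg.seed, "ann1", s.repeat_id)) for s in scores],
            columns=["repeat_id", "diff_sum", "penalties", "total",
                     "repeat_seed"]),
            Path(outdir) / "scores.csv", cfg)
        rows = []
        for (lvl, sid), m in mean.items():
            for yr, mv, sv in zip(m.years, m.values, se[(lvl, sid)].values):
                rows.append((lvl, sid, yr, mv, sv))
        _write_csv(pd.DataFrame(
            rows, columns=["grazing_level", "scenario", "year", "mean", "se"]),
            Path(outdir) / "forecast_mean_se.csv", cfg)
    return result


# --- stage: cross-validation -----------------------------------------------

def run_crossval(cfg: RunConfig, world: World,
                 outdir: Path | None = None) -> pd.DataFrame:
    """In-sample and leave-one-site-out peak-location report per site."""
    sites = build_sites(world, cfg)
    if len(sites) < 2:
        raise InputError("cross-validation needs >= 2 sites")
    spec = ann.deposition_network_spec()
    tcfg = ann.TrainConfig(fractions=cfg.ann1_crossval_fractions,
                           max_iterations=cfg.max_iterations,
                           seed=derive_seed(cfg.seed, "crossval-insample"))
    net = ann.train_best_of(spec, sites, tcfg,
                            n_repeats=cfg.crossval_repeats,
                            detect_params=cfg.detect,
                            default_window=cfg.default_window,
                            seed_label="insample")

    loso = ann.loso_crossval(
        sites, spec,
        ann.TrainConfig(fractions=cfg.ann1_crossval_fractions,
                        max_iterations=cfg.max_iterations,
                        seed=derive_seed(cfg.seed, "crossval")),
        detect_params=cfg.detect, default_window=cfg.default_window,
        n_repeats=cfg.crossval_repeats)

    rows = []
    for s, held in zip(sites, loso):
        x, _, _, years = s.design(spec.delay_range)
        in_curve = AnnualSeries(years, net.predict_matrix(x))
        t_peaks = selection.detect_peaks(
            s.target.as_series().window(in_curve.start, in_curve.end),
            cfg.detect, site=s.name)
        in_peaks = selection.detect_peaks(in_curve, cfg.detect, site=s.name)
        win = selection.peak_window(t_peaks, cfg.default_window)
        in_score = selection.score_repeat({s.name: in_peaks},
                                          {s.name: t_peaks}, win)
        rows.append({
            "site": s.name,
            "n_target_peaks": len(t_peaks),
            "window": win,
            "in_sample_total": in_score.total,
            "in_sample_penalties": in_score.penalty_count,
            "oos_total": held["score"].total,
            "oos_penalties": held["score"].penalty_count,
        })
    report = pd.DataFrame(rows)
    if outdir is not None:
        _write_csv(report, Path(outdir) / "crossval.csv", cfg)
    return report


# --- full run ---------------------------------------------------------------

def full_run(cfg: RunConfig, outdir: str | Path) -> dict:
    """Simulate, cross-validate, forecast; write all artefacts + manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    world = generate_world(cfg.world)
    write_world(world, outdir / "world")
    crossval = run_crossval(cfg, world, outdir)
    futures = run_ann2_stage(cfg, world, outdir)
    forecasts = run_ann1_stage(cfg, world, futures, outdir)

    m2 = futures.mean[2]
    rho = float(np.median([
        spearmanr(m2.values,
                  forecasts.mean[(lvl, 4)].values[-len(m2):]).statistic
        for lvl in ("low", "moderate", "heavy")]))
    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "ann1_repeats": cfg.ann1_repeats,
        "ann2_repeats": cfg.ann2_repeats,
        "peak_window": forecasts.window,
        "treering_repeats_kept": futures.n_kept,
        "oos_sites_without_penalty": int(
            (crossval["oos_penalties"] == 0).sum()),
        "antiphase_spearman_climate2": rho,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"world": world, "crossval": crossval, "futures": futures,
            "forecasts": forecasts, "manifest": manifest}
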