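# Methods

This note records the model as implemented, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and
the numerical choices a maintainer would want to know.

## The two-network chain

The quantity being predicted is a *deposition event score*: a per-site,
per-year curve whose relative peaks mark years in which a dated sediment
deposition event is likely to be found.  It is constructed from the
site's OSL ages as an equal-weight mixture of Gaussian densities (one per
age, width = its 1σ dating error), min–max rescaled to [0, 1] per site.
Rescaling is per site and independent: only relative peak positions carry
meaning downstream, and a common [0, 1] range stabilises training.  Long
runs (≥ 20 years by default) of near-zero score (< 1e-6 of the site
maximum) are masked out of the training loss — a dune profile that shows
no dated event in a stretch of years says nothing about stability there,
and training on those zeros would teach the network that the
corresponding driver conditions stabilise the surface.  Masked years are
excluded from every error and Jacobian term, but the underlying input
years still feed the delay line of later rows.

**Deposition network.**  Inputs: tree-ring growth index (RLOESS-smoothed,
span 0.2), grazing-pressure index (centred moving average, window 0.1 of
the series length), binary wildfire occurrence.  Each input enters at
lags 0–8 years ("up to 8 years" read as lags 0 through 8 inclusive), so
the design row has 3 × 9 = 27 features; the first 8 years of the grid are
dropped, and multiple sites are embedded independently and stacked, so no
row mixes years across sites.  Architecture: hidden layers [3, 30, 30, 3],
tanh activations, linear scalar output.

**Tree-ring network.**  Inputs: growing-season precipitation and average
max/min temperature, RLOESS-smoothed at span 0.2, no delay line; one
9-neuron tanh hidden layer.  The training target is the tree-ring index
smoothed with the same span as the inputs.  The smoother is (near-)linear,
so smoothing both sides preserves the linear climate→growth relation
while removing the annual noise the smoothed inputs no longer carry; an
unsmoothed target would cap the achievable R² well below 1 even for a
noise-free generator.

**Training.**  Levenberg–Marquardt: Δw = (JᵀJ + μI)⁻¹Jᵀe over training
rows, with the Jacobian assembled analytically by backpropagating output
sensitivities.  μ starts at 1e-3, ×10 on a rejected step (training SSE
not reduced), ÷10 on acceptance, abort above 1e10.  Inputs and targets
are min–max scaled to [−1, 1] column-wise (constant columns map to 0);
weights initialise uniform [−0.5, 0.5] × fan-in⁻¹ᐟ², seeded.  Rows are
partitioned at random by individual year — validation and test counts are
round(fraction·n), remainder to training — into 90/5/5 (cross-validation
runs), 50/5/45 (scenario-forecast runs; the large test share guards
against over-fitting a short series) or 70/10/20 (tree-ring network).
Year-wise random partitioning leaks autocorrelated neighbours between
partitions; that is the quoted behaviour of the original design and is
documented rather than "fixed".  Training stops at the iteration cap, on
μ overflow, or after 6 consecutive iterations without a validation
improvement; the returned weights are the best-validation ones.

## Peak-location model selection

A repeat's quality is the summed timing error of its predicted peaks, not
its MSE.  Peaks are local maxima with prominence ≥ 0.1 × curve maximum
and ≥ 5 years separation (both configurable; the detector is
deterministic).  The peak window is half the spacing of the two closest
known peaks across the target dataset, floored (a 26-year minimum spacing
gives 13); with fewer than two target peaks the default window 13 is
used.  Each target peak is matched greedily, nearest pair first, to an
unused predicted peak within ± window; matched peaks add |Δyears|,
unmatched target peaks add 1e6, and *extra* predicted peaks cost nothing
— a deliberate asymmetry: an unrecorded event may simply have eroded away.
Peaks are evaluated only over years the delay line allows the network to
predict (the first 8 grid years have no prediction, and a curve cannot
have a detectable maximum at its own boundary).  Scores sum over sites;
the lowest-scoring 10 % of repeats (ties by repeat id) form the forecast
ensemble, summarised per year as mean and sd/√k.

Cross-validation (in-sample and leave-one-site-out) trains a small number
of repeats per fold (3 by default) and keeps the repeat that best
reproduces the *training* sites' peaks — the same selection metric, never
applied to the held-out site.

## Scenarios

AR noise is fitted per climate variable by least squares on the
mean-removed historical series (order 1 by default; coefficients clamped
below unit modulus with a warning if the fit is non-stationary).  Climate
1 is mean + AR noise; climate 2 adds a linear ramp on both temperature
series from 0 in 2015 to +4.5 °F in 2098 ("end of the century" = 2098,
the last simulated year).  Within one assembly the two climates share a
single noise draw, so paired scenarios differ only by the prescribed
trend.  The 1998–2014 "measured" segment is a clearly-labelled synthetic
stand-in drawn from the fitted noise model with a dedicated seed.
Grazing levels low/moderate/heavy are encoded 1/2/3 (the ordinal scale of
the source index is unpublished; the encoding is arbitrary and recorded
here); the pulse adds +1 for 2059–2068 and is refused on the heavy base —
scenario bundles 2 and 5 are then built without it and flagged.  The fire
rule sets fire = 1 exactly when average maximum temperature is strictly
above 80 °F.  Scenario prediction inputs are prepended with the last 8
historical years so forecasts start in 1998.

## The synthetic world

The generator emulates the statistical structure the analysis assumes,
not any real record:

* climate = long-term mean + AR(1) noise (φ = 0.3; sd 3 in / 2 °F / 2 °F
  around 18 in / 82 °F / 55 °F — plausible Great-Plains growing-season
  values);
* tree-ring index = 2000 + 50·precip − 20·tmax + N(0, 50), truncated at
  0.  The scale (≈ 1,000–1,500) is chosen so the extreme-value screen
  (> 5,000) is meaningful; the real index's scale is not published;
* grazing: piecewise-constant regimes (default 1 → 2 → 3 → 2 across the
  1590–1997 window); fire ~ Bernoulli(0.03 + 0.02·(tmax − mean), clipped);
* deposition: a standardized mobility score (drought z × 1.0 + heat z ×
  0.6 + grazing excess × 0.25 + fire × 0.5) is thresholded at 2.7; each
  upward crossing, lagged 2 years, is a deposition event.  The threshold
  was calibrated once so the default world yields ≈ 5–10 events per 400
  years, the visual density of the empirical targets.  Each site keeps an
  event with probability 0.7 (erosional censoring) and records it with
  N(0, 10 yr) dating error (reported σ floored at 1 year so the density
  target is always defined).  Ground truth (parameters, true event years)
  is always emitted beside the observed files, never inside them.

What the generator does *not* emulate: spatial structure within a dune,
age-depth inversion, heteroscedastic dating errors growing with age,
non-stationary climate regimes, or management responses to fire.  Passing
tests therefore demonstrate that the pipeline recovers relationships *of
the assumed form* from data with realistic noise, censoring and dating
error — not that the real system satisfies those forms.

## Problem sizes and reproducibility

Publication-scale ensembles are 8,000 tree-ring repeats, 5,000 deposition
repeats and a 300-iteration cap (`full=True` / `--full`).  Desk-scale
defaults are 500 / 200 repeats with the cap at 120 iterations; validation
patience usually stops training far earlier, so the cap mostly bounds the
occasional long run, and repeat counts trade Monte-Carlo precision only —
the code path is identical.  The test suite and the acceptance script
scale further (tens of repeats), which is enough for the rule constants
and recovery checks but leaves the qualitative scenario contrasts
visibly noisier than a full-scale run.  The strong-warming scenario also
pushes the tree-ring input below the network's historical training
range, so any *single* grazing level's growth/deposition rank
correlation is extrapolation-sensitive at small ensemble sizes; the
antiphase diagnostic is therefore reported as the median correlation
across the three grazing levels, which is stable at desk scale.

Every random draw descends from one master seed through
`numpy.random.SeedSequence` (stable across platforms and processes);
per-repeat, per-site and per-stage streams use fixed labelled offsets, so
adding sites or repeats never perturbs existing draws, and a fixed seed
fixes every output bit-for-bit.  Output CSVs carry the configuration hash
and seed in a comment header; `manifest.json` summarises each full run.

## Known limitations

* One shared grazing/fire history for all sites (per-site inputs are
  supported by the data structures but the generator emits shared ones).
* The deposition network's scalar output head predicts one site at a
  time from shared inputs: multi-site training fits the conditional mean
  of the sites' targets.
* Greedy nearest-first peak matching is not globally optimal (a rare
  crossed-pair configuration can over-count by a few years).
* The AR generator and the AR fitter are order-configurable, but all
  shipped defaults are order 1.
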