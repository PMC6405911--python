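"""Input smoothing and construction of the deposition-likelihood target.

The networks are not trained on raw annual records.  Driver series are
smoothed — the tree-ring index (and, for the climate→tree-ring network, the
climate inputs) by robust LOESS with a span of 0.2, the grazing index by a
centred moving average with a 0.1 window fraction — and the target is a
per-site probability-density curve built by stacking Gaussian kernels at
each OSL age (width = its 1-sigma dating error).  Long runs of near-zero
target are masked out of training: a dune profile records deposition, not
stability, so an empty stretch is absence of evidence and must not teach
the model that those years' conditions were stabilising.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .series import AnnualSeries, ConfigurationError
from .synthetic import OSLAgeRecord


@dataclass
class DepositionPDF:
    """Per-site deposition-event-score target with a training mask."""
    site: str
    years: np.ndarray
    score: np.ndarray       # non-negative, min-max rescaled to [0, 1]
    train_mask: np.ndarray  # False on long near-zero gaps (excluded from loss)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=np.int64)
        self.score = np.asarray(self.score, dtype=np.float64)
        self.train_mask = np.asarray(self.train_mask, dtype=bool)
        if not (self.years.shape == self.score.shape == self.train_mask.shape):
            raise ValueError("years, score and train_mask must share one shape")
        if np.any(self.score < 0):
            raise ValueError("score must be non-negative")

    def as_series(self) -> AnnualSeries:
        return AnnualSeries(self.years, self.score, units="score",
                            name=f"target_{self.site}")


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    return w


def _wls_line(x: np.ndarray, y: np.ndarray, w: np.ndarray, x0: float) -> float:
    """Weighted local-linear fit evaluated at x0 (normal equations)."""
    sw = w.sum()
    if sw <= 0:
        return float(np.nan)
    xm = (w * x).sum() / sw
    ym = (w * y).sum() / sw
    dx = x - xm
    sxx = (w * dx * dx).sum()
    if sxx <= 1e-12 * max(sw, 1.0):
        return float(ym)
    slope = (w * dx * (y - ym)).sum() / sxx
    return float(ym + slope * (x0 - xm))


def rloess_smooth(series: AnnualSeries, span_fraction: float = 0.2,
                  robust_iterations: int = 3) -> AnnualSeries:
    """Robust locally weighted regression (RLOESS) on an annual grid.

    Local linear fits over the ``round(span_fraction * n)`` nearest
    neighbours of each year, tricube distance weights, followed by
    ``robust_iterations`` reweighting passes with bisquare weights on the
    residuals (scale = 6 * median absolute residual), which down-weights
    outlying years.
    """
    n = len(series)
    if n < 10:
        raise ConfigurationError("series too short to smooth (need >= 10 years)")
    window = int(round(span_fraction * n))
    if window < 3:
        raise ConfigurationError(
            f"smoothing window {window} < 3 (span_fraction too small)")
    window = min(window, n)
    x = series.years.astype(float)
    y = series.values
    robust_w = np.ones(n)
    fitted = y.copy()
    for _ in range(robust_iterations + 1):
        new = np.empty(n)
        for i in range(n):
            lo = min(max(i - window // 2, 0), n - window)
            idx = slice(lo, lo + window)
            xi, yi, rwi = x[idx], y[idx], robust_w[idx]
            d = np.abs(xi - x[i])
            dmax = d.max()
            w = _tricube(d / dmax if dmax > 0 else d) * rwi
            new[i] = _wls_line(xi, yi, w, x[i])
        fitted = new
        resid = y - fitted
        s = 6.0 * np.median(np.abs(resid))
        if s <= 0:
            break
        u = resid / s
        robust_w = np.where(np.abs(u) < 1.0, (1.0 - u ** 2) ** 2, 0.0)
    return series.with_values(fitted)


def moving_average(series: AnnualSeries, factor: float = 0.1) -> AnnualSeries:
    """Centred moving mean with window = max(1, round(factor * n)).

    Windows shrink at the series edges (truncated, not padded), so the
    output stays on the input grid.  Even windows are centred with the
    extra point on the trailing side.
    """
    n = len(series)
    window = max(1, int(round(factor * n)))
    if window == 1:
        return series.with_values(series.values.copy())
    half_lead = (window - 1) // 2
    half_trail = window - 1 - half_lead
    out = np.empty(n)
    csum = np.concatenate([[0.0], np.cumsum(series.values)])
    for i in range(n):
        lo = max(0, i - half_trail)
        hi = min(n, i + half_lead + 1)
        out[i] = (csum[hi] - csum[lo]) / (hi - lo)
    return series.with_values(out)


def build_age_pdf(ages: list[OSLAgeRecord], years: np.ndarray,
                  site: str | None = None) -> DepositionPDF:
    """Stacked-Gaussian likelihood curve from a site's OSL age list.

    score_t = (1/n) * sum_i N(t; age_i, sigma_i), then min-max rescaled to
    [0, 1].  Only relative peak positions matter downstream, so the
    absolute density scale is dropped.  An empty age list yields an
    all-zero score with an all-false mask.
    """
    years = np.asarray(years, dtype=np.int64)
    name = site if site is not None else (ages[0].site if ages else "?")
    if not ages:
        z = np.zeros(years.size)
        return DepositionPDF(name, years, z, np.zeros(years.size, dtype=bool))
    if any(a.sigma_years <= 0 for a in ages):
        raise ValueError("all dating errors must be strictly positive")
    score = np.zeros(years.size)
    # fixed accumulation order makes the curve independent of list order
    for a in sorted(ages, key=lambda r: (r.age_year, r.sigma_years)):
        score += norm.pdf(years.astype(float), loc=a.age_year, scale=a.sigma_years)
    score /= len(ages)
    lo, hi = score.min(), score.max()
    if hi > lo:
        score = (score - lo) / (hi - lo)
    return DepositionPDF(name, years, score, np.ones(years.size, dtype=bool))


def build_age_pdf_raw(ages: list[OSLAgeRecord], years: np.ndarray) -> np.ndarray:
    """Un-rescaled mixture density (integrates to ~1 over a wide grid)."""
    years = np.asarray(years, dtype=float)
    score = np.zeros(years.size)
    for a in sorted(ages, key=lambda r: (r.age_year, r.sigma_years)):
        score += norm.pdf(years, loc=a.age_year, scale=a.sigma_years)
    return score / max(len(ages), 1)


def mask_zero_gaps(pdf: DepositionPDF, gap_years: int = 20,
                   eps_fraction: float = 1e-6) -> DepositionPDF:
    """Mask training on long contiguous near-zero runs of the target.

    Any run of at least ``gap_years`` consecutive years with
    score < eps_fraction * max(score) gets ``train_mask = False``.  Scores
    are never altered; shorter runs stay trainable.
    """
    if gap_years < 1:
        raise ConfigurationError("gap_years must be >= 1")
    peak = pdf.score.max()
    mask = pdf.train_mask.copy()
    if peak <= 0:
        return DepositionPDF(pdf.site, pdf.years.copy(), pdf.score.copy(), mask)
    low = pdf.score < eps_fraction * peak
    n = low.size
    i = 0
    while i < n:
        if low[i]:
            j = i
            while j < n and low[j]:
                j += 1
            if j - i >= gap_years:
                mask[i:j] = False
            i = j
        else:
            i += 1
    return DepositionPDF(pdf.site, pdf.years.copy(), pdf.score.copy(), mask)


def site_targets(sites: dict[str, list[OSLAgeRecord]], years: np.ndarray,
                 gap_years: int = 20, eps_fraction: float = 1e-6,
                 ) -> dict[str, DepositionPDF]:
    """Build the masked per-site training targets in one call."""
    return {
        name: mask_zero_gaps(build_age_pdf(ages, years, site=name),
                             gap_years=gap_years, eps_fraction=eps_fraction)
        for name, ages in sites.items()
    }
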