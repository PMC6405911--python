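"""Ensemble screening, peak-location scoring and top-fraction selection.

Model quality is judged by *where* the predicted deposition peaks fall,
not how big they are: the geomorphic response is binary (sediment moves or
it does not), so a repeat is scored by summing, over every target peak at
every site, the |offset in years| to the nearest unused predicted peak
within the peak window — or a large penalty (1e6) when no predicted peak
falls inside the window.  Ensembles are screened for runaway repeats
(more than seven simulated tree-ring values above 5,000), the lowest-score
10% of repeats is kept, and the survivors are summarised as a per-year
mean and standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .series import AnnualSeries, ConfigurationError, InputError

PENALTY = 1e6
EXTREME_VALUE_THRESHOLD = 5000.0
EXTREME_COUNT_THRESHOLD = 7
TOP_FRACTION = 0.10
DEFAULT_WINDOW = 13


@dataclass
class PeakDetectParams:
    prominence_fraction: float = 0.1   # of the curve maximum
    min_separation: int = 5            # years


@dataclass
class PeakSet:
    """Sorted peak years of one site's curve."""
    site: str
    years: np.ndarray
    params: PeakDetectParams = field(default_factory=PeakDetectParams)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=np.int64)
        if self.years.size > 1 and np.any(np.diff(self.years) <= 0):
            raise ValueError("peak years must be strictly increasing")

    def __len__(self) -> int:
        return self.years.size


@dataclass
class RepeatScore:
    """Peak-location score of one ensemble repeat."""
    repeat_id: int
    diff_sum: float          # summed |location difference| over matched peaks
    penalty_count: int       # target peaks with no predicted peak in window
    penalty_value: float = PENALTY

    @property
    def total(self) -> float:
        return self.diff_sum + self.penalty_count * self.penalty_value


def screen_extreme(repeats: list[np.ndarray],
                   value_thresh: float = EXTREME_VALUE_THRESHOLD,
                   count_thresh: int = EXTREME_COUNT_THRESHOLD,
                   ) -> list[int]:
    """Indices of repeats retained by the extreme-value screen.

    A repeat is excluded when it contains *more than* ``count_thresh``
    values strictly above ``value_thresh``; exactly ``count_thresh`` such
    values is still retained.
    """
    if value_thresh <= 0 or count_thresh <= 0:
        raise ConfigurationError("screening thresholds must be positive")
    keep = []
    for i, r in enumerate(repeats):
        if int(np.sum(np.asarray(r) > value_thresh)) <= count_thresh:
            keep.append(i)
    return keep


def detect_peaks(curve: AnnualSeries, params: PeakDetectParams | None = None,
                 site: str = "") -> PeakSet:
    """Local maxima with prominence >= prominence_fraction * max(curve) and
    pairwise separation >= min_separation years.  Deterministic; may be
    empty (e.g. monotone curves)."""
    params = params or PeakDetectParams()
    if len(curve) < 3:
        return PeakSet(site, np.array([], dtype=int), params)
    top = float(np.max(curve.values))
    if top <= 0 or not np.isfinite(top):
        return PeakSet(site, np.array([], dtype=int), params)
    idx, _ = find_peaks(curve.values,
                        prominence=params.prominence_fraction * top,
                        distance=max(params.min_separation, 1))
    return PeakSet(site, curve.years[idx], params)


def peak_window(target_peaks: PeakSet,
                default_window: int = DEFAULT_WINDOW) -> int:
    """Half the minimum spacing between known peaks (floored).

    With fewer than two target peaks there is no spacing to halve and the
    default window is returned.
    """
    if len(target_peaks) == 0:
        raise InputError("empty target peak set")
    if len(target_peaks) < 2:
        return default_window
    return int(np.min(np.diff(target_peaks.years)) // 2)


def global_peak_window(targets: dict[str, PeakSet],
                       default_window: int = DEFAULT_WINDOW) -> int:
    """One window for the whole target dataset: half the spacing of the two
    closest known peaks across all sites."""
    spacings = [int(np.min(np.diff(p.years)))
                for p in targets.values() if len(p) >= 2]
    if not spacings:
        return default_window
    return min(spacings) // 2


def _match_site(pred: np.ndarray, targ: np.ndarray, window: int
                ) -> tuple[float, int]:
    """Greedy nearest-first matching; each predicted peak used at most once."""
    pairs = []
    for ti, ty in enumerate(targ):
        for pi, py in enumerate(pred):
            d = abs(int(py) - int(ty))
            if d <= window:
                pairs.append((d, ti, pi))
    pairs.sort()
    used_t: set[int] = set()
    used_p: set[int] = set()
    diff_sum = 0.0
    for d, ti, pi in pairs:
        if ti in used_t or pi in used_p:
            continue
        used_t.add(ti)
        used_p.add(pi)
        diff_sum += d
    return diff_sum, len(targ) - len(used_t)


def score_repeat(predicted: dict[str, PeakSet], targets: dict[str, PeakSet],
                 window: int, penalty: float = PENALTY,
                 repeat_id: int = 0) -> RepeatScore:
    """Sum peak-location differences and penalties across sites.

    For each site, every target peak is matched to the nearest unused
    predicted peak within +/-window years (nearest pairs claimed first);
    matched peaks contribute |offset|, unmatched target peaks contribute
    the penalty.  Extra predicted peaks with no target counterpart cost
    nothing.
    """
    if window < 1:
        raise ConfigurationError("peak window must be >= 1 year")
    diff_sum = 0.0
    penalties = 0
    for site, targ in targets.items():
        pred = predicted.get(site, PeakSet(site, np.array([], dtype=int)))
        d, miss = _match_site(pred.years, targ.years, window)
        diff_sum += d
        penalties += miss
    return RepeatScore(repeat_id, diff_sum, penalties, penalty)


def select_top(scores: list[RepeatScore],
               fraction: float = TOP_FRACTION) -> list[RepeatScore]:
    """The ceil(fraction * n) lowest-scoring repeats; ties broken by id."""
    if not (0.0 < fraction <= 1.0):
        raise ConfigurationError("fraction must be in (0, 1]")
    n_keep = int(np.ceil(fraction * len(scores)))
    ranked = sorted(scores, key=lambda s: (s.total, s.repeat_id))
    return ranked[:n_keep]


def summarize(curves: list[AnnualSeries]) -> tuple[AnnualSeries, AnnualSeries]:
    """Per-year mean and standard error (sd / sqrt(k)) of selected repeats."""
    if len(curves) < 2:
        raise InputError("need >= 2 curves to summarise")
    years = curves[0].years
    for c in curves[1:]:
        if not np.array_equal(c.years, years):
            raise InputError("curves are not on one shared grid")
    stack = np.vstack([c.values for c in curves])
    mean = stack.mean(axis=0)
    se = stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0])
    se[np.ptp(stack, axis=0) == 0.0] = 0.0  # identical repeats: exactly zero
    return (AnnualSeries(years, mean, units=curves[0].units, name="mean"),
            AnnualSeries(years, se, units=curves[0].units, name="se"))
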