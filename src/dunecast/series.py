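"""Annual time-series container used throughout the pipeline.

All pipeline data live on contiguous integer-year grids (calendar years AD).
:class:`AnnualSeries` is a thin, immutable-by-convention wrapper around a
year vector and a value vector with a units tag; it deliberately does not
try to be a general time-series class — pandas is used at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd


class ConfigurationError(ValueError):
    """A configuration value violates its documented contract."""


class GridAlignmentError(ValueError):
    """Series that must share one year grid do not."""


class InputError(ValueError):
    """Input data violate an operation's precondition."""


@dataclass
class AnnualSeries:
    """Real-valued annual series on a contiguous integer-year grid.

    Parameters
    ----------
    years
        Strictly increasing, step-1 integer calendar years (AD).
    values
        One value per year.
    units
        Free-text units tag (e.g. ``"inches"``, ``"degF"``, ``"index"``).
    name
        Variable name used in file output and diagnostics.
    """

    years: np.ndarray
    values: np.ndarray
    units: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.years.ndim != 1 or self.values.shape != self.years.shape:
            raise InputError("years and values must be 1-d arrays of equal length")
        if self.years.size == 0:
            raise InputError("empty series")
        if self.years.size > 1 and not np.all(np.diff(self.years) == 1):
            raise InputError("year grid must be contiguous with step 1")

    def __len__(self) -> int:
        return self.years.size

    @property
    def start(self) -> int:
        return int(self.years[0])

    @property
    def end(self) -> int:
        return int(self.years[-1])

    def with_values(self, values: np.ndarray, name: str | None = None) -> "AnnualSeries":
        """Same grid and units, new values (copies metadata)."""
        return AnnualSeries(
            self.years.copy(), np.asarray(values, dtype=float),
            units=self.units, name=self.name if name is None else name,
        )

    def window(self, start: int, end: int) -> "AnnualSeries":
        """Inclusive year-range slice; raises if outside the grid."""
        if start < self.start or end > self.end or start > end:
            raise InputError(
                f"window [{start},{end}] outside series grid [{self.start},{self.end}]"
            )
        i0 = start - self.start
        i1 = end - self.start + 1
        return AnnualSeries(self.years[i0:i1], self.values[i0:i1],
                            units=self.units, name=self.name)

    def value_at(self, year: int) -> float:
        if not (self.start <= year <= self.end):
            raise InputError(f"year {year} outside grid")
        return float(self.values[year - self.start])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "value": self.values})

    @classmethod
    def constant(cls, start: int, end: int, value: float, **kw) -> "AnnualSeries":
        years = np.arange(start, end + 1)
        return cls(years, np.full(years.size, float(value)), **kw)


def require_same_grid(*series: AnnualSeries) -> np.ndarray:
    """Return the shared year grid, or raise :class:`GridAlignmentError`."""
    if not series:
        raise InputError("no series given")
    ref = series[0].years
    for s in series[1:]:
        if s.years.shape != ref.shape or not np.array_equal(s.years, ref):
            raise GridAlignmentError("series are not on one shared year grid")
    return ref


def concat_years(a: AnnualSeries, b: AnnualSeries) -> AnnualSeries:
    """Concatenate two abutting series (b starts the year after a ends)."""
    if b.start != a.end + 1:
        raise GridAlignmentError(
            f"cannot concatenate: {a.end} followed by {b.start}"
        )
    return AnnualSeries(
        np.concatenate([a.years, b.years]),
        np.concatenate([a.values, b.values]),
        units=a.units, name=a.name,
    )
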