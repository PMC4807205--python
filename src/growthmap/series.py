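"""Annual rate series, cumulative targets, and standardization.

The observable is an annual crude rate per 100,000 inhabitants (``s_t``),
read as the year-on-year increment -- the discrete derivative -- of a latent
cumulative level (``S_t``).  The cumulative series obtained by running
summation from a base year is the level variable the growth maps are fitted
to, and both the target and every candidate orbit are compared on a common
dimensionless scale after z-standardization.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AnnualRateSeries",
    "CumulativeSeries",
    "StandardizedSeries",
    "read_rate_table",
    "build_cumulative",
    "standardize",
    "load_italy_total",
]


@dataclass(frozen=True)
class AnnualRateSeries:
    """A year-indexed series of crude rates.

    Parameters
    ----------
    years
        Strictly increasing integer calendar years.
    rates
        One finite, non-negative rate per year (per 100,000 inhabitants).
    label
        Free-text series name, e.g. ``"total"``, ``"male"``, ``"female"``.
    allow_gaps
        Missing calendar years are rejected unless this flag is set.  A
        gapped series can be stored and plotted but never accumulated:
        running summation requires contiguous years.
    """

    years: np.ndarray
    rates: np.ndarray
    label: str = ""
    allow_gaps: bool = False

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=int)
        rates = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "rates", rates)
        if years.ndim != 1 or rates.ndim != 1 or len(years) != len(rates):
            raise ValueError("years and rates must be 1-D and equally long")
        if len(years) == 0:
            raise ValueError("no observations")
        if len(years) > 1:
            d = np.diff(years)
            if np.any(d <= 0):
                bad = years[1:][d <= 0]
                raise ValueError(
                    f"years must be strictly increasing; duplicate or "
                    f"out-of-order year(s) {bad.tolist()}"
                )
            if np.any(d > 1) and not self.allow_gaps:
                gaps = years[:-1][d > 1]
                raise ValueError(
                    f"missing year(s) after {gaps.tolist()}; pass "
                    f"allow_gaps=True to store a gapped series"
                )
        if not np.all(np.isfinite(rates)):
            raise ValueError("rates must be finite")
        if np.any(rates < 0):
            bad_years = years[rates < 0]
            raise ValueError(f"negative rate(s) at year(s) {bad_years.tolist()}")

    def __len__(self) -> int:
        return len(self.years)

    @property
    def has_gaps(self) -> bool:
        return len(self.years) > 1 and bool(np.any(np.diff(self.years) > 1))

    def rate_at(self, year: int) -> float:
        idx = np.searchsorted(self.years, year)
        if idx >= len(self.years) or self.years[idx] != year:
            raise KeyError(f"year {year} not in series")
        return float(self.rates[idx])

    def window(self, start_year: int, end_year: int) -> "AnnualRateSeries":
        mask = (self.years >= start_year) & (self.years <= end_year)
        return AnnualRateSeries(self.years[mask], self.rates[mask],
                                label=self.label, allow_gaps=self.allow_gaps)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "rate": self.rates})


@dataclass(frozen=True)
class CumulativeSeries:
    """Running sums of annual rates from a base year.

    ``values[i]`` is the sum of the rates from ``base_year`` through
    ``years[i]``; differencing recovers the source rates exactly (up to
    accumulation round-off), and the values are non-decreasing whenever all
    contributing rates are non-negative.
    """

    base_year: int
    years: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "years", np.asarray(self.years, dtype=int))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if len(self.years) != len(self.values):
            raise ValueError("years and values must be equally long")

    @property
    def n_obs(self) -> int:
        return len(self.values)

    def __len__(self) -> int:
        return len(self.values)

    def window(self, start_year: int, end_year: int) -> "CumulativeSeries":
        """Slice to [start_year, end_year]; sums still accumulate from base_year."""
        mask = (self.years >= start_year) & (self.years <= end_year)
        if not mask.any():
            raise ValueError(f"window [{start_year}, {end_year}] is empty")
        return CumulativeSeries(self.base_year, self.years[mask], self.values[mask])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "cumulative": self.values})


@dataclass(frozen=True)
class StandardizedSeries:
    """A z-scored series together with the moments that produced it.

    The scale is the population standard deviation (denominator ``n``); the
    z-values therefore have mean 0 and population SD 1 by construction.
    """

    z_values: np.ndarray
    mean: float
    sd: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "z_values", np.asarray(self.z_values, dtype=float))


def read_rate_table(
    path,
    label: str = "",
    delimiter: str | None = None,
    year_col: str = "year",
    rate_col: str = "rate",
    allow_gaps: bool = False,
) -> AnnualRateSeries:
    """Read a delimited year/rate text table into a validated series.

    Lines starting with ``#`` are treated as comments.  Rows are sorted by
    year; duplicate years, negative rates and unparseable cells are rejected
    with a row-identifying message.
    """
    try:
        df = pd.read_csv(path, sep=delimiter, comment="#",
                         engine="python" if delimiter is None else "c",
                         skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no observations") from None
    if df.empty:
        raise ValueError(f"{path}: no observations")
    for col in (year_col, rate_col):
        if col not in df.columns:
            raise ValueError(
                f"{path}: missing column {col!r} (found {list(df.columns)})")
    years = pd.to_numeric(df[year_col], errors="coerce")
    rates = pd.to_numeric(df[rate_col], errors="coerce")
    bad = years.isna() | rates.isna() | (years != years.round())
    if bad.any():
        rows = (df.index[bad] + 2).tolist()  # 1-based, plus header line
        raise ValueError(f"{path}: unparseable year/rate at file row(s) {rows}")
    order = np.argsort(years.to_numpy())
    y = years.to_numpy(dtype=int)[order]
    r = rates.to_numpy(dtype=float)[order]
    dup = np.unique(y[np.flatnonzero(np.diff(y) == 0)])
    if dup.size:
        raise ValueError(f"{path}: duplicate year(s) {dup.tolist()}")
    if np.any(r < 0):
        raise ValueError(
            f"{path}: negative rate(s) at year(s) {y[r < 0].tolist()}")
    return AnnualRateSeries(y, r, label=label, allow_gaps=allow_gaps)


def build_cumulative(
    series: AnnualRateSeries,
    base_year: int | None = None,
    end_year: int | None = None,
) -> CumulativeSeries:
    """Accumulate rates from ``base_year`` through ``end_year``.

    Both bounds must be present in the series and the window must be free of
    calendar gaps; missing years are a hard error, never interpolated.
    """
    if base_year is None:
        base_year = int(series.years[0])
    if end_year is None:
        end_year = int(series.years[-1])
    if end_year < base_year:
        raise ValueError(f"end_year {end_year} precedes base_year {base_year}")
    for y in (base_year, end_year):
        if y not in series.years:
            raise ValueError(f"year {y} not present in series")
    mask = (series.years >= base_year) & (series.years <= end_year)
    yrs = series.years[mask]
    expected = np.arange(base_year, end_year + 1)
    if len(yrs) != len(expected) or np.any(yrs != expected):
        missing = sorted(set(expected.tolist()) - set(yrs.tolist()))
        raise ValueError(f"missing year(s) {missing} in accumulation window")
    return CumulativeSeries(base_year, yrs, np.cumsum(series.rates[mask]))


def standardize(values) -> StandardizedSeries:
    """z = (x - M) / sigma with sigma the population SD (denominator n)."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("standardize requires a 1-D series of length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input")
    m = float(x.mean())
    sd = float(x.std())  # population convention, ddof=0
    if sd == 0.0:
        raise ValueError("zero variance: constant input cannot be standardized")
    return StandardizedSeries((x - m) / sd, m, sd)


def load_italy_total() -> AnnualRateSeries:
    """The packaged Italian total-population series, 1873-2010."""
    ref = importlib.resources.files("growthmap.data") / "italy_suicide_total.csv"
    with importlib.resources.as_file(ref) as p:
        return read_rate_table(p, label="total")
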