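"""Data model and CSV I/O for uniformly sampled sensor series with gaps.

A :class:`Series` is a single scalar channel sampled at a strictly constant
cadence (10 minutes by default, i.e. 144 samples per day).  Missingness is
carried as an explicit boolean mask — never as a sentinel value — and a
contiguous missing segment is described by a :class:`GapSpec`.

Indexing is 0-based throughout; a gap covers the half-open index range
``[start, start + length)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

DEFAULT_CADENCE = pd.Timedelta(minutes=10)

#: canonical covariate column names in the CSV dialect
COVARIATE_COLUMNS = ("air_humidity", "par", "soil_temperature")


@dataclass(frozen=True)
class Series:
    """Uniformly sampled scalar channel with an explicit missing mask.

    Parameters
    ----------
    values
        Float array; entries at masked positions are ignored (stored as NaN).
    mask
        Boolean array, ``True`` where the value is missing.
    start_time
        Timestamp of index 0.
    cadence
        Strictly positive sampling interval; index ``i`` maps to
        ``start_time + i * cadence``.
    channel_name
        Physical channel, e.g. ``"stem_moisture"`` (volumetric water
        content, percent).
    """

    values: np.ndarray
    mask: np.ndarray = None  # type: ignore[assignment]
    start_time: pd.Timestamp = field(default_factory=lambda: pd.Timestamp("2017-06-01"))
    cadence: pd.Timedelta = DEFAULT_CADENCE
    channel_name: str = "stem_moisture"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 1:
            raise ValueError("series must be one-dimensional with length >= 1")
        mask = self.mask
        if mask is None:
            mask = np.isnan(values)
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != values.shape:
            raise ValueError("mask shape must match values shape")
        if self.cadence <= pd.Timedelta(0):
            raise ValueError("cadence must be strictly positive")
        values = values.copy()
        values[mask] = np.nan
        observed = values[~mask]
        if self.channel_name == "stem_moisture" and observed.size:
            if observed.min() < 0.0 or observed.max() > 100.0:
                raise ValueError("stem moisture values must lie in [0, 100] percent")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "mask", mask)
        self.values.setflags(write=False)
        self.mask.setflags(write=False)

    def __len__(self) -> int:
        return self.values.size

    @property
    def n_missing(self) -> int:
        return int(self.mask.sum())

    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_time, periods=len(self), freq=self.cadence)

    def with_values(self, values: np.ndarray, mask: np.ndarray | None = None) -> "Series":
        return replace(self, values=np.asarray(values, dtype=float), mask=mask)


@dataclass(frozen=True)
class GapSpec:
    """A contiguous missing segment: 0-based start index and positive length."""

    start: int
    length: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError("gap start must be >= 0")
        if self.length < 1:
            raise ValueError("gap length must be a positive integer")

    @property
    def stop(self) -> int:
        """Exclusive end index."""
        return self.start + self.length

    def indices(self) -> np.ndarray:
        return np.arange(self.start, self.stop)

    def check_bounds(self, n: int) -> None:
        if self.stop > n:
            raise ValueError(
                f"gap [{self.start}, {self.stop}) exceeds series length {n}"
            )

    def mirrored(self, n: int) -> "GapSpec":
        """The same gap seen from the time-reversed series of length *n*."""
        self.check_bounds(n)
        return GapSpec(start=n - self.stop, length=self.length)


def read_series_csv(
    path,
    column_map: dict | None = None,
) -> Series:
    """Read a Series from the package CSV dialect.

    The dialect has a header row with a ``timestamp`` column (ISO-8601) and a
    ``value`` column; empty or non-numeric value cells mark missing samples.
    ``column_map`` may rename columns (``{"timestamp": ..., "value": ...}``),
    override ``channel_name``, or supply a ``cadence`` default used when the
    file holds a single row.
    """
    column_map = dict(column_map or {})
    ts_col = column_map.get("timestamp", "timestamp")
    val_col = column_map.get("value", "value")
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"empty CSV file: {path}")
    if ts_col not in df.columns or val_col not in df.columns:
        raise ValueError(f"CSV must contain columns {ts_col!r} and {val_col!r}")
    timestamps = pd.to_datetime(df[ts_col])
    values = pd.to_numeric(df[val_col], errors="coerce").to_numpy(dtype=float)
    if len(df) == 1:
        cadence = pd.Timedelta(column_map.get("cadence", DEFAULT_CADENCE))
    else:
        deltas = timestamps.diff().iloc[1:]
        cadence = deltas.iloc[0]
        bad = np.nonzero((deltas != cadence).to_numpy())[0]
        if bad.size:
            # +2: offset into deltas plus 1-based human row numbering
            raise ValueError(
                f"non-uniform cadence at row {int(bad[0]) + 2}: expected {cadence}"
            )
    return Series(
        values=values,
        start_time=timestamps.iloc[0],
        cadence=cadence,
        channel_name=column_map.get("channel_name", "stem_moisture"),
    )


def write_series_csv(path, series: Series, covariates: dict[str, Series] | None = None,
                     source: np.ndarray | None = None) -> None:
    """Write a Series (plus optional aligned covariate channels) to CSV.

    Values are written with 8 significant digits; missing cells are empty.
    ``source`` optionally adds a per-row provenance column
    (``observed``/``filled``).
    """
    df = pd.DataFrame({"timestamp": series.timestamps(), "value": series.values})
    for name, cov in (covariates or {}).items():
        if len(cov) != len(series):
            raise ValueError(f"covariate {name!r} length mismatch")
        df[name] = cov.values
    if source is not None:
        df["source"] = source
    df.to_csv(path, index=False, float_format="%.8g")


def mask_gap(series: Series, gap: GapSpec) -> Series:
    """Return a copy of *series* with the gap indices marked missing.

    The input series must be fully observed on the gap and is left unchanged.
    """
    gap.check_bounds(len(series))
    if series.mask[gap.start : gap.stop].any():
        raise ValueError("gap range already contains missing values")
    mask = series.mask.copy()
    mask[gap.start : gap.stop] = True
    return series.with_values(series.values, mask=mask)


def reverse(series: Series) -> Series:
    """Time-reverse a series (values and mask); an involution."""
    return series.with_values(series.values[::-1], mask=series.mask[::-1])


@dataclass(frozen=True)
class MinMaxTransform:
    """Invertible affine map sending ``[lo, hi]`` to ``[0, 1]``."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.hi > self.lo:
            raise ValueError("degenerate fit segment: zero value range")

    def apply(self, x):
        return (np.asarray(x, dtype=float) - self.lo) / (self.hi - self.lo)

    def invert(self, y):
        return np.asarray(y, dtype=float) * (self.hi - self.lo) + self.lo


def minmax_normalize(
    series: Series, fit_segment: slice | np.ndarray | None = None
) -> tuple[Series, MinMaxTransform]:
    """Min-max normalize a series, fitting the range on *fit_segment* only.

    The fit segment (an index slice or index array; default: all observed
    points) must contain at least two distinct observed values.  Returns the
    normalized series and the invertible transform.
    """
    if fit_segment is None:
        seg_values = series.values[~series.mask]
    else:
        seg_values = series.values[fit_segment]
        seg_mask = series.mask[fit_segment]
        seg_values = seg_values[~seg_mask]
    seg_values = seg_values[~np.isnan(seg_values)]
    if seg_values.size < 2 or seg_values.min() == seg_values.max():
        raise ValueError("fit segment needs >= 2 distinct observed values")
    transform = MinMaxTransform(lo=float(seg_values.min()), hi=float(seg_values.max()))
    normalized = replace(
        series,
        values=transform.apply(series.values),
        mask=series.mask.copy(),
        channel_name=f"{series.channel_name}_normalized",
    )
    return normalized, transform
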