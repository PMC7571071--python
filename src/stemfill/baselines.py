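"""Classical gap-filling comparators: interpolation and ARMA/ARIMA forecasts.

Interpolation bridges the gap through context points on *both* flanks
(natural cubic spline or shape-preserving PCHIP); forecasting fits an
ARMA/ARIMA model on the *pre-gap* context only and fills the gap with its
multi-step forecast.  Interpolation quality collapses once the gap grows
past a fraction of the diurnal period — the motivation for the recurrent
filling method — and :func:`gap_length_sweep` quantifies that decay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline, PchipInterpolator

from .core_series import GapSpec, Series, mask_gap
from .fill import FillResult
from .metrics import ErrorReport, error_report

INTERP_METHODS = ("spline", "pchip")
FORECAST_METHODS = ("arma", "arima")


@dataclass(frozen=True)
class BaselineConfig:
    """Configuration for the classical fill methods."""

    method: str = "spline"
    arma_order: tuple[int, int] | str = "auto"
    arima_order: tuple[int, int, int] | str = "auto"
    max_order_for_auto: tuple[int, int, int] = (5, 2, 5)
    context_length: int = 1000

    def __post_init__(self) -> None:
        if self.method not in INTERP_METHODS + FORECAST_METHODS:
            raise ValueError(f"unknown baseline method {self.method!r}")
        if self.context_length < 1:
            raise ValueError("context_length must be positive")


def fill_interpolation(
    series: Series,
    gap: GapSpec,
    method: str = "spline",
    context_length: int = 1000,
) -> FillResult:
    """Bridge a gap with a cubic interpolant through both flanks.

    ``spline`` is a natural cubic spline, ``pchip`` the shape-preserving
    piecewise cubic Hermite interpolant (monotone on monotone data, no
    overshoot).  Requires at least 4 observed context points on each flank.
    """
    if method not in INTERP_METHODS:
        raise ValueError(f"unknown interpolation method {method!r}")
    gap.check_bounds(len(series))
    left = np.arange(max(0, gap.start - context_length), gap.start)
    right = np.arange(gap.stop, min(len(series), gap.stop + context_length))
    left = left[~series.mask[left]]
    right = right[~series.mask[right]]
    if left.size < 4 or right.size < 4:
        raise ValueError(
            f"need >= 4 observed points on each flank (have {left.size} left, "
            f"{right.size} right)"
        )
    x = np.concatenate([left, right])
    y = series.values[x]
    if method == "spline":
        interp = CubicSpline(x, y, bc_type="natural")
    else:
        interp = PchipInterpolator(x, y)
    filled = interp(gap.indices())
    return FillResult(
        scheme=f"baseline:{method}",
        gap=gap,
        filled=filled,
        provenance={"method": method, "context_length": context_length,
                    "flanks": "both"},
    )


def _auto_order(values: np.ndarray, d: int, max_p: int, max_q: int):
    """AIC order selection over a small (p, q) grid at fixed d."""
    from statsmodels.tsa.arima.model import ARIMA

    best = None
    diagnostics = []
    for p in range(max_p + 1):
        for q in range(max_q + 1):
            if p == 0 and q == 0:
                continue
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = ARIMA(values, order=(p, d, q)).fit()
                if np.isfinite(fit.aic) and (best is None or fit.aic < best[0]):
                    best = (fit.aic, (p, d, q), fit)
            except Exception as exc:  # non-convergent candidate order
                diagnostics.append(((p, d, q), str(exc)))
    if best is None:
        raise RuntimeError(f"no ARIMA order converged; tried: {diagnostics}")
    return best[1], best[2]


def fill_forecast(
    series: Series,
    gap: GapSpec,
    method: str = "arima",
    config: BaselineConfig | None = None,
) -> FillResult:
    """Fill a gap with the multi-step forecast of an ARMA/ARIMA model fitted
    by maximum likelihood on the pre-gap context only."""
    from statsmodels.tsa.arima.model import ARIMA

    if method not in FORECAST_METHODS:
        raise ValueError(f"unknown forecast method {method!r}")
    config = config or BaselineConfig(method=method)
    gap.check_bounds(len(series))
    ctx = np.arange(max(0, gap.start - config.context_length), gap.start)
    if ctx.size == 0 or series.mask[ctx].any():
        raise ValueError("pre-gap context must be observed and non-empty")
    values = series.values[ctx]
    order = config.arma_order if method == "arma" else config.arima_order
    max_p, max_d, max_q = config.max_order_for_auto
    if order == "auto":
        d = 0 if method == "arma" else 1
        order, fit = _auto_order(values, d, max_p, max_q)
    else:
        if method == "arma":
            order = (order[0], 0, order[1])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = ARIMA(values, order=tuple(order)).fit()
    filled = np.asarray(fit.forecast(steps=gap.length))
    return FillResult(
        scheme=f"baseline:{method}",
        gap=gap,
        filled=filled,
        provenance={"method": method, "order": tuple(order),
                    "context_length": config.context_length,
                    "flanks": "pre-gap only"},
    )


DEFAULT_SWEEP_LENGTHS = (10, 20, 30, 40, 50, 100, 150, 200)


def gap_length_sweep(
    series: Series,
    lengths: tuple[int, ...] = DEFAULT_SWEEP_LENGTHS,
    method: str = "spline",
    context_length: int = 1000,
    center: int | None = None,
) -> dict[int, ErrorReport]:
    """Interpolation/forecast error as a function of gap length.

    Masks gaps of each requested length around a fixed center of the fully
    observed *series*, fills them with *method*, and reports the error per
    length.  Infeasible lengths are skipped with a warning.
    """
    if series.mask.any():
        raise ValueError("sweep needs a fully observed truth series")
    n = len(series)
    center = n // 2 if center is None else center
    reports: dict[int, ErrorReport] = {}
    for L in lengths:
        start = center - L // 2
        if start < 4 or start + L > n - 4:
            warnings.warn(f"gap length {L} infeasible at center {center}; skipped",
                          stacklevel=2)
            continue
        gap = GapSpec(start=start, length=L)
        masked = mask_gap(series, gap)
        if method in INTERP_METHODS:
            result = fill_interpolation(masked, gap, method, context_length)
        else:
            result = fill_forecast(masked, gap, method,
                                   BaselineConfig(method=method,
                                                  context_length=context_length))
        reports[L] = error_report(result.filled, series.values[gap.start:gap.stop])
    return reports
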