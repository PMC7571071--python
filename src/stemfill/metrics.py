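"""Error statistics for gap-filling results.

Two unit conventions coexist in the report, and they are deliberate:

* ``maximum``, ``minimum`` and ``mape`` are *relative* errors
  e = |x_p − x| / x (dimensionless), reported ×100;
* ``mae`` and ``rmse`` are *absolute* deviations in the target's own units
  (percentage points of volumetric water content for stem moisture).

With truth near 50 % this makes MAE ≈ MAPE / 2, the relationship the
method's error tables exhibit.  The threshold proportions count the share
of points whose relative error does not exceed 0.01 … 0.05, reported as a
percentage of points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_THRESHOLDS = (0.01, 0.02, 0.03, 0.04, 0.05)


def relative_error(predicted: float, truth: float) -> float:
    """e = |x_p − x| / x; defined only for positive truth values."""
    if not truth > 0:
        raise ValueError("relative error undefined for truth <= 0")
    return abs(predicted - truth) / truth


@dataclass(frozen=True)
class ErrorReport:
    """The five error statistics plus the thresholded error distribution."""

    maximum: float  # max relative error, %
    minimum: float  # min relative error, %
    mae: float      # mean absolute error, target units (percentage points)
    mape: float     # mean relative error, %
    rmse: float     # root mean squared error, target units
    threshold_proportions: dict[float, float] = field(default_factory=dict)
    n: int = 0

    def __post_init__(self) -> None:
        if self.minimum > self.maximum:
            raise ValueError("minimum exceeds maximum")
        if self.mae > self.rmse * (1 + 1e-12):
            raise ValueError("MAE cannot exceed RMSE")
        props = list(self.threshold_proportions.values())
        if any(p < 0 or p > 100 for p in props):
            raise ValueError("threshold proportions must lie in [0, 100]")
        if any(b < a - 1e-12 for a, b in zip(props, props[1:])):
            raise ValueError("threshold proportions must be non-decreasing")

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "maximum": self.maximum,
            "minimum": self.minimum,
            "mae": self.mae,
            "mape": self.mape,
            "rmse": self.rmse,
            "thresholds": {str(k): v for k, v in self.threshold_proportions.items()},
        }


def error_report(
    predicted: np.ndarray,
    truth: np.ndarray,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> ErrorReport:
    """Full error report for a filled segment against the ground truth."""
    predicted = np.asarray(predicted, dtype=float).reshape(-1)
    truth = np.asarray(truth, dtype=float).reshape(-1)
    if predicted.size != truth.size:
        raise ValueError("predicted and truth must have equal length")
    if predicted.size < 1:
        raise ValueError("need at least one point")
    if not (truth > 0).all():
        raise ValueError("truth values must all be positive")
    rel = np.abs(predicted - truth) / truth
    abs_dev = np.abs(predicted - truth)
    proportions = {
        float(thr): float((rel <= thr).mean() * 100.0) for thr in sorted(thresholds)
    }
    return ErrorReport(
        maximum=float(rel.max() * 100.0),
        minimum=float(rel.min() * 100.0),
        mae=float(abs_dev.mean()),
        mape=float(rel.mean() * 100.0),
        rmse=float(np.sqrt(np.mean(abs_dev**2))),
        threshold_proportions=proportions,
        n=predicted.size,
    )


def compare_methods(results, truth) -> pd.DataFrame:
    """One ErrorReport row per FillResult against the same truth.

    *results* is a list of FillResult objects sharing one gap; *truth* is the
    fully observed Series.  Rows keep input order.  Columns give the five
    statistics followed by the threshold proportions.
    """
    from .fill import FillResult  # local import to avoid a cycle

    if not results:
        raise ValueError("need at least one FillResult")
    gap = results[0].gap
    for r in results:
        if r.gap != gap:
            raise ValueError("all results must share the same gap")
    truth_vals = truth.values[gap.start : gap.stop]
    if np.isnan(truth_vals).any():
        raise ValueError("truth must be observed on the gap")
    rows = []
    for r in results:
        rep = error_report(r.filled, truth_vals)
        row = {
            "scheme": r.scheme,
            "n": rep.n,
            "maximum": rep.maximum,
            "minimum": rep.minimum,
            "mae": rep.mae,
            "mape": rep.mape,
            "rmse": rep.rmse,
        }
        for thr, p in rep.threshold_proportions.items():
            row[f"le_{thr:g}"] = p
        rows.append(row)
    return pd.DataFrame(rows)
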