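"""Recursive window-push gap filling and bidirectional fusion.

The filling recursion takes the ``window_length`` observed values adjacent
to the gap, predicts the next value, appends the prediction to the end of
the window, drops the oldest value, and repeats until the gap is covered.
Because predictions progressively replace observations in the window, the
error of a directional fill accumulates along the gap — the behaviour the
bidirectional fusion schemes are designed to offset.

Three fusion schemes combine a forward fill x (model trained on pre-gap
data) with a reverse fill y (model trained on the time-reversed post-gap
data), per gap index i:

* equal weights:        z_i = 0.5·x_i + 0.5·y_i
* decreasing weights:   z_i = a_i·x_i + b_i·y_i, with a descending from
  1.00 to 0.05 in 0.05 steps across the gap and b = 1 − a ascending from
  0.00 to 0.95;
* segmented:            forward values on the first half of the gap,
  reverse values on the second half (a junction discontinuity is expected
  and deliberately not smoothed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_series import GapSpec, MinMaxTransform, Series, minmax_normalize, reverse
from .nn import ArchitectureSpec, make_training_windows, predict_next, train

SCHEMES = ("forward", "reverse", "bidir_equal", "bidir_decreasing", "bidir_segmented")


@dataclass(frozen=True)
class FillResult:
    """Filled values for one gap, with fusion weights when bidirectional."""

    scheme: str
    gap: GapSpec
    filled: np.ndarray
    weights: np.ndarray | None = None  # (L, 2) rows (a_i, b_i), bidirectional only
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        filled = np.asarray(self.filled, dtype=float)
        object.__setattr__(self, "filled", filled)
        if filled.size != self.gap.length:
            raise ValueError("filled length must equal gap length")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != (self.gap.length, 2):
                raise ValueError("weights must be (gap length, 2)")
            if not np.allclose(w.sum(axis=1), 1.0, atol=1e-12):
                raise ValueError("fusion weights must sum to 1 per index")
            object.__setattr__(self, "weights", w)

    def apply_to(self, series: Series) -> Series:
        """Substitute the filled values into a masked copy of *series*;
        observed values are never altered."""
        values = series.values.copy()
        mask = series.mask.copy()
        values[self.gap.start : self.gap.stop] = self.filled
        mask[self.gap.start : self.gap.stop] = False
        return series.with_values(values, mask=mask)


def fill_directional(
    model,
    series: Series,
    gap: GapSpec,
    direction: str = "forward",
) -> FillResult:
    """Recursive window-push fill of one gap in one direction.

    *model* is anything with ``architecture.window_length``,
    ``architecture.input_features == 1``, an optional ``transform`` and a
    batched ``predict`` — a :class:`~stemfill.nn.TrainedModel` or a test
    oracle.  The ``window_length`` values adjacent to the gap (preceding it
    for ``forward``, following it for ``reverse``) must be observed.
    Predictions are fed back verbatim in normalized space (no clipping);
    denormalization happens once at the end.  A reverse fill runs the same
    recursion on the time-reversed series and is re-aligned to forward index
    order before returning.
    """
    if direction not in ("forward", "reverse"):
        raise ValueError(f"unknown direction {direction!r}")
    gap.check_bounds(len(series))
    if direction == "reverse":
        rev_result = fill_directional(
            model, reverse(series), gap.mirrored(len(series)), "forward"
        )
        return FillResult(
            scheme="reverse",
            gap=gap,
            filled=rev_result.filled[::-1],
            provenance=rev_result.provenance,
        )

    w = model.architecture.window_length
    if gap.start < w:
        raise ValueError(
            f"need {w} observed values before the gap; only {gap.start} available"
        )
    run_up = slice(gap.start - w, gap.start)
    if series.mask[run_up].any():
        raise ValueError("run-up window before the gap contains missing values")
    transform: MinMaxTransform | None = getattr(model, "transform", None)
    buffer = series.values[run_up].astype(float)
    if transform is not None:
        buffer = transform.apply(buffer)
    preds = np.empty(gap.length)
    for k in range(gap.length):
        p = predict_next(model, buffer)
        preds[k] = p
        buffer = np.append(buffer[1:], p)
    filled = transform.invert(preds) if transform is not None else preds
    return FillResult(
        scheme="forward",
        gap=gap,
        filled=filled,
        provenance={"window_length": w, "direction": "forward"},
    )


def _check_pair(forward: FillResult, reverse_: FillResult) -> None:
    if forward.gap != reverse_.gap:
        raise ValueError("forward and reverse results must share the same gap")


def combine_equal(forward: FillResult, reverse_: FillResult) -> FillResult:
    """Equal-weight fusion: z_i = 0.5 x_i + 0.5 y_i."""
    _check_pair(forward, reverse_)
    L = forward.gap.length
    weights = np.full((L, 2), 0.5)
    return FillResult(
        scheme="bidir_equal",
        gap=forward.gap,
        filled=0.5 * forward.filled + 0.5 * reverse_.filled,
        weights=weights,
        provenance={"forward": forward.provenance, "reverse": reverse_.provenance},
    )


def decreasing_weight_schedule(length: int, gradient: float = 0.05) -> np.ndarray:
    """Per-index (a_i, b_i) pairs of the decreasing-weight scheme.

    The forward weight descends 1.00, 0.95, …, 0.05 (``0.95 / gradient + 1``
    levels) and b = 1 − a.  The gap is partitioned into that many consecutive
    blocks of near-equal size, each block sharing one weight pair; remainders
    go to the earliest blocks.
    """
    n_steps = 0.95 / gradient
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError("gradient must divide 0.95 evenly")
    n_levels = int(round(n_steps)) + 1
    a_levels = 1.0 - gradient * np.arange(n_levels)
    base, rem = divmod(length, n_levels)
    block_sizes = np.full(n_levels, base)
    block_sizes[:rem] += 1
    a = np.repeat(a_levels, block_sizes)
    return np.column_stack([a, 1.0 - a])


def combine_decreasing(
    forward: FillResult, reverse_: FillResult, gradient: float = 0.05
) -> FillResult:
    """Decreasing-weight fusion: forward weight 1.00 → 0.05 across the gap."""
    _check_pair(forward, reverse_)
    weights = decreasing_weight_schedule(forward.gap.length, gradient)
    filled = weights[:, 0] * forward.filled + weights[:, 1] * reverse_.filled
    return FillResult(
        scheme="bidir_decreasing",
        gap=forward.gap,
        filled=filled,
        weights=weights,
        provenance={"gradient": gradient, "forward": forward.provenance,
                    "reverse": reverse_.provenance},
    )


def combine_segmented(forward: FillResult, reverse_: FillResult) -> FillResult:
    """Segmented fusion: forward fill on the first ⌈L/2⌉ indices, reverse on
    the rest."""
    _check_pair(forward, reverse_)
    L = forward.gap.length
    split = -(-L // 2)  # ceiling
    filled = np.concatenate([forward.filled[:split], reverse_.filled[split:]])
    return FillResult(
        scheme="bidir_segmented",
        gap=forward.gap,
        filled=filled,
        provenance={"split": split, "forward": forward.provenance,
                    "reverse": reverse_.provenance},
    )


_COMBINERS = {
    "bidir_equal": combine_equal,
    "bidir_decreasing": combine_decreasing,
    "bidir_segmented": combine_segmented,
}


@dataclass(frozen=True)
class FillTrainConfig:
    """Training configuration for :func:`fill_bidirectional`."""

    epochs: int = 100
    learning_rate: float = 1e-3
    train_length: int | None = None  # observed points used per side (None: all)


def _directional_fills(
    arch: ArchitectureSpec,
    series: Series,
    gap: GapSpec,
    cfg: FillTrainConfig,
    seed: int,
    need_forward: bool,
    need_reverse: bool,
) -> tuple[FillResult | None, FillResult | None]:
    gap.check_bounds(len(series))
    w = arch.window_length
    n = len(series)
    pre_len = gap.start
    post_len = n - gap.stop
    if need_forward and pre_len < w + 1:
        raise ValueError(
            f"insufficient data on the forward (pre-gap) side: "
            f"{pre_len} points, need {w + 1}"
        )
    if need_reverse and post_len < w + 1:
        raise ValueError(
            f"insufficient data on the reverse (post-gap) side: "
            f"{post_len} points, need {w + 1}"
        )

    t_len = cfg.train_length
    pre_seg = slice(max(0, pre_len - t_len) if t_len else 0, gap.start)
    post_stop = min(n, gap.stop + t_len) if t_len else n
    post_seg = slice(gap.stop, post_stop)
    fit_idx = np.r_[np.arange(pre_seg.start, pre_seg.stop),
                    np.arange(post_seg.start, post_seg.stop)]
    normalized, transform = minmax_normalize(series, fit_segment=fit_idx)

    fwd_result = rev_result = None
    if need_forward:
        windows, targets = make_training_windows(normalized, w, segment=pre_seg)
        fwd_model = train(arch, windows, targets, epochs=cfg.epochs, seed=seed,
                          learning_rate=cfg.learning_rate, transform=transform)
        fwd_result = fill_directional(fwd_model, series, gap, "forward")
    if need_reverse:
        rev_norm = reverse(normalized)
        rev_seg = slice(n - post_seg.stop, n - post_seg.start)
        windows, targets = make_training_windows(rev_norm, w, segment=rev_seg)
        rev_model = train(arch, windows, targets, epochs=cfg.epochs, seed=seed + 1,
                          learning_rate=cfg.learning_rate, transform=transform)
        rev_result = fill_directional(rev_model, series, gap, "reverse")
    return fwd_result, rev_result


def fill_bidirectional(
    arch: ArchitectureSpec,
    series: Series,
    gap: GapSpec,
    scheme: str = "bidir_decreasing",
    train_config: FillTrainConfig | None = None,
    seed: int = 0,
) -> FillResult:
    """Train directional models and fill one gap with the requested scheme.

    A forward model is trained on the pre-gap segment and a reverse model on
    the time-reversed post-gap segment, with independent seeds derived from
    the master seed (``seed`` and ``seed + 1``).  Both share one min-max
    normalization fitted on the training segments only.  ``scheme`` may also
    be ``forward`` or ``reverse`` for a single directional fill.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    cfg = train_config or FillTrainConfig()
    fwd_result, rev_result = _directional_fills(
        arch, series, gap, cfg, seed,
        need_forward=scheme != "reverse",
        need_reverse=scheme != "forward",
    )
    if scheme == "forward":
        result = fwd_result
    elif scheme == "reverse":
        result = rev_result
    else:
        result = _COMBINERS[scheme](fwd_result, rev_result)
    provenance = {"seed": seed, "epochs": cfg.epochs,
                  "window_length": arch.window_length, **result.provenance}
    return FillResult(
        scheme=result.scheme,
        gap=result.gap,
        filled=result.filled,
        weights=result.weights,
        provenance=provenance,
    )


def fill_all_schemes(
    arch: ArchitectureSpec,
    series: Series,
    gap: GapSpec,
    train_config: FillTrainConfig | None = None,
    seed: int = 0,
) -> dict[str, FillResult]:
    """All five schemes from one pair of directional trainings.

    Trains the forward and reverse models once (seeds ``seed`` / ``seed + 1``,
    exactly as :func:`fill_bidirectional`) and returns a scheme→FillResult
    mapping for forward, reverse and the three fusions.
    """
    cfg = train_config or FillTrainConfig()
    fwd, rev = _directional_fills(arch, series, gap, cfg, seed,
                                  need_forward=True, need_reverse=True)
    return {
        "forward": fwd,
        "reverse": rev,
        "bidir_equal": combine_equal(fwd, rev),
        "bidir_decreasing": combine_decreasing(fwd, rev),
        "bidir_segmented": combine_segmented(fwd, rev),
    }
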