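"""Covariate-driven (multivariate) stem-moisture filling.

Instead of recursing on its own predictions, this model maps a window of
environmental covariates — air humidity (AH, %), photosynthetically active
radiation (PAR, µmol m⁻² s⁻¹) and soil temperature (ST, °C) — to the stem
moisture value at the window's final timestamp.  Every gap index is
predicted independently from observed covariates, so there is no feedback
and no error accumulation: the fill length is limited only by covariate
coverage, not by the window length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_series import GapSpec, MinMaxTransform, Series
from .fill import FillResult
from .metrics import error_report
from .nn import ArchitectureSpec, TrainedModel, stacked_architecture, train

CHANNEL_ALIASES = {"AH": "air_humidity", "PAR": "par", "ST": "soil_temperature"}

#: the seven input subsets of the channel-selection comparison
DEFAULT_SUBSETS = (
    ("AH",), ("PAR",), ("ST",),
    ("AH", "PAR"), ("AH", "ST"), ("PAR", "ST"),
    ("AH", "PAR", "ST"),
)


def _canonical(channel: str) -> str:
    return CHANNEL_ALIASES.get(channel, channel)


@dataclass
class CovariateFrame:
    """Aligned covariate channels plus the stem-moisture target."""

    target: Series
    covariates: dict[str, Series]
    input_subset: tuple[str, ...] = ("AH", "PAR", "ST")

    def __post_init__(self) -> None:
        self.input_subset = tuple(_canonical(c) for c in self.input_subset)
        if not self.input_subset:
            raise ValueError("input subset must be nonempty")
        n = len(self.target)
        for name in self.input_subset:
            if name not in self.covariates:
                raise ValueError(f"missing covariate channel {name!r}")
            cov = self.covariates[name]
            if len(cov) != n or cov.cadence != self.target.cadence:
                raise ValueError(f"covariate {name!r} misaligned with target")

    def covariate_matrix(self) -> np.ndarray:
        """(n, features) matrix of the selected covariates, in subset order."""
        return np.column_stack(
            [self.covariates[name].values for name in self.input_subset]
        )


@dataclass
class CovariateModel:
    """A trained covariate→moisture model plus per-channel normalization."""

    model: TrainedModel
    input_subset: tuple[str, ...]
    covariate_transforms: dict[str, MinMaxTransform]
    window_length: int


def covariate_architecture(
    n_layers: int = 3,
    units: int = 50,
    dropout_fraction: float | None = 0.2,
    window_length: int = 144,
    input_features: int = 3,
    batch_size: int = 100,
) -> ArchitectureSpec:
    """LSTM stack for covariate filling; the reference variants are 2×50,
    3×50, and 3×50 with dropout (keep-probability 0.8, i.e. drop 0.2)."""
    return stacked_architecture(
        "lstm",
        tuple([units] * n_layers),
        dropout_fraction=dropout_fraction,
        window_length=window_length,
        batch_size=batch_size,
        input_features=input_features,
    )


def _build_windows(
    frame: CovariateFrame,
    window_length: int,
    transforms: dict[str, MinMaxTransform],
    target_transform: MinMaxTransform | None,
    segment: slice,
) -> tuple[np.ndarray, np.ndarray | None]:
    X = frame.covariate_matrix()[segment]
    for j, name in enumerate(frame.input_subset):
        X = X.copy()
        X[:, j] = transforms[name].apply(X[:, j])
    L = X.shape[0]
    if L < window_length:
        raise ValueError("segment shorter than the covariate window")
    k = L - window_length + 1
    idx = np.arange(window_length)[None, :] + np.arange(k)[:, None]
    windows = X[idx]
    targets = None
    if target_transform is not None:
        y = frame.target.values[segment][window_length - 1 :]
        targets = target_transform.apply(y)
    return windows, targets


def train_covariate_model(
    frame: CovariateFrame,
    arch: ArchitectureSpec | None = None,
    *,
    train_segment: slice | None = None,
    epochs: int = 100,
    seed: int = 0,
    learning_rate: float = 1e-3,
) -> CovariateModel:
    """Fit the covariate→moisture model on an observed segment of the frame.

    The model consumes a ``window_length`` stretch of the selected covariate
    channels (ending at time t) and predicts stem moisture at t.  Each
    channel gets its own min-max normalization fitted on the training
    segment; the target transform rides along for denormalization.
    """
    arch = arch or covariate_architecture(input_features=len(frame.input_subset))
    if arch.input_features != len(frame.input_subset):
        raise ValueError(
            f"architecture expects {arch.input_features} input features but the "
            f"frame selects {len(frame.input_subset)} channels"
        )
    segment = train_segment or slice(0, len(frame.target))
    if frame.target.mask[segment].any():
        raise ValueError("training segment of the target contains missing values")
    transforms = {}
    for name in frame.input_subset:
        vals = frame.covariates[name].values[segment]
        lo, hi = float(vals.min()), float(vals.max())
        if hi == lo:
            hi = lo + 1.0  # constant channel: degenerate but harmless
        transforms[name] = MinMaxTransform(lo=lo, hi=hi)
    t_vals = frame.target.values[segment]
    target_transform = MinMaxTransform(lo=float(t_vals.min()), hi=float(t_vals.max()))
    windows, targets = _build_windows(
        frame, arch.window_length, transforms, target_transform, segment
    )
    model = train(arch, windows, targets, epochs=epochs, seed=seed,
                  learning_rate=learning_rate, transform=target_transform)
    return CovariateModel(
        model=model,
        input_subset=frame.input_subset,
        covariate_transforms=transforms,
        window_length=arch.window_length,
    )


def fill_from_covariates(
    cov_model: CovariateModel,
    frame: CovariateFrame,
    gap: GapSpec,
) -> FillResult:
    """Predict every gap index independently from its covariate window.

    Covariates must be observed over ``[gap.start − window + 1, gap.stop)``;
    the target may be missing anywhere.  There is no recursion: the fill
    length is unbounded by the window and the per-index predictions are
    order-independent.
    """
    gap.check_bounds(len(frame.target))
    w = cov_model.window_length
    lo = gap.start - w + 1
    if lo < 0:
        raise ValueError("not enough covariate history before the gap")
    for name in cov_model.input_subset:
        seg_mask = frame.covariates[name].mask[lo : gap.stop]
        if seg_mask.any():
            bad = lo + int(np.nonzero(seg_mask)[0][0])
            raise ValueError(f"covariate {name!r} missing at index {bad}")
    X = np.column_stack(
        [cov_model.covariate_transforms[name].apply(frame.covariates[name].values)
         for name in cov_model.input_subset]
    )
    idx = np.arange(w)[None, :] + (np.arange(gap.length) + lo)[:, None]
    windows = X[idx]
    preds = cov_model.model.predict(windows)
    filled = cov_model.model.transform.invert(preds)
    return FillResult(
        scheme="covariate",
        gap=gap,
        filled=filled,
        provenance={"inputs": list(cov_model.input_subset), "window_length": w},
    )


#: the three covariate-model variants compared in the reference study:
#: (n_layers, units, dropout_fraction) — 2×50, 3×50, 3×50 with keep-prob 0.8
DEFAULT_ARCH_VARIANTS = ((2, 50, None), (3, 50, None), (3, 50, 0.2))


def compare_architectures(
    frame: CovariateFrame,
    gap: GapSpec,
    variants: tuple[tuple[int, int, float | None], ...] = DEFAULT_ARCH_VARIANTS,
    *,
    window_length: int = 144,
    train_segment: slice | None = None,
    epochs: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Fill error of several covariate-model depth/width/dropout variants on
    one frame, one row per (n_layers, units, dropout) triple."""
    rows = []
    for n_layers, units, dropout in variants:
        arch = covariate_architecture(
            n_layers=n_layers, units=units, dropout_fraction=dropout,
            window_length=window_length, input_features=len(frame.input_subset),
        )
        cov_model = train_covariate_model(
            frame, arch, train_segment=train_segment, epochs=epochs, seed=seed
        )
        result = fill_from_covariates(cov_model, frame, gap)
        rep = error_report(result.filled, frame.target.values[gap.start:gap.stop])
        label = f"{n_layers}*{units}" + (f"*{1 - dropout:g}" if dropout else "")
        rows.append({"model": label, **rep.to_dict()})
    df = pd.DataFrame(rows)
    return df.drop(columns=["thresholds"]).join(
        pd.json_normalize(df["thresholds"]).add_prefix("le_")
    )


def compare_input_subsets(
    frame: CovariateFrame,
    gap: GapSpec,
    subsets: tuple[tuple[str, ...], ...] = DEFAULT_SUBSETS,
    *,
    arch_units: tuple[int, int] = (3, 50),
    window_length: int = 144,
    dropout_fraction: float | None = 0.2,
    train_segment: slice | None = None,
    epochs: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Train one model per covariate subset under identical configuration and
    report its fill error on the gap (the truth target must be observed
    there).  Defaults to the seven canonical subsets."""
    n_layers, units = arch_units
    rows = []
    for subset in subsets:
        if not subset:
            raise ValueError("subsets must be nonempty")
        sub_frame = CovariateFrame(
            target=frame.target, covariates=frame.covariates, input_subset=subset
        )
        arch = covariate_architecture(
            n_layers=n_layers, units=units, dropout_fraction=dropout_fraction,
            window_length=window_length, input_features=len(subset),
        )
        cov_model = train_covariate_model(
            sub_frame, arch, train_segment=train_segment, epochs=epochs, seed=seed
        )
        result = fill_from_covariates(cov_model, sub_frame, gap)
        truth = frame.target.values[gap.start : gap.stop]
        rep = error_report(result.filled, truth)
        rows.append({"inputs": " + ".join(subset), **rep.to_dict()})
    df = pd.DataFrame(rows)
    return df.drop(columns=["thresholds"]).join(
        pd.json_normalize(df["thresholds"]).add_prefix("le_")
    )
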