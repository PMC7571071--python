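"""Synthetic stem-moisture series and correlated environmental covariates.

Stem water content of a healthy tree oscillates with the sunrise/sunset
cycle: it is drawn down during the day (transpiration) and recharges at
night, riding on a slow multi-day trend plus autocorrelated sensor noise.
The generator emulates that qualitative structure — a single diurnal
sinusoid (144 samples/day at the default 10-minute cadence), a smooth random
trend, and AR(1) Gaussian noise, clipped to a physical band (43–57 % by
default).  It is deliberately *not* a mechanistic plant model; the filling
methods only assume regular diurnal fluctuation.

Covariates (air humidity, photosynthetically active radiation, soil
temperature) are built to hit target Pearson correlations with the moisture
signal, defaulting to values representative of field observations on tree
stems: AH ≈ +0.57, ST ≈ +0.29, PAR ≈ −0.30.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core_series import GapSpec, Series, mask_gap

#: default target Pearson correlations of each covariate with stem moisture
DEFAULT_COVARIATE_CORRELATIONS = {
    "air_humidity": 0.57,
    "par": -0.30,
    "soil_temperature": 0.29,
}

#: physical rescaling of the standardized covariate signals: (mean, sd, low clip)
_COVARIATE_SCALES = {
    "air_humidity": (60.0, 15.0, 0.0, 100.0),   # percent RH
    "par": (500.0, 400.0, 0.0, None),           # µmol m⁻² s⁻¹, rectified
    "soil_temperature": (22.0, 3.0, None, None),  # °C
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the diurnal stem-moisture simulator (all in percent
    volumetric water content unless noted)."""

    n_days: int = 16
    samples_per_day: int = 144
    base_level: float = 50.0
    diurnal_amplitude: float = 5.0
    trend_amplitude: float = 1.5
    noise_sd: float = 0.3
    noise_ar1: float = 0.7
    value_band: tuple[float, float] = (43.0, 57.0)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.value_band
        if not lo < hi:
            raise ValueError("value_band low must be < high")
        if self.samples_per_day < 2:
            raise ValueError("samples_per_day must be >= 2")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if not 0.0 <= self.noise_ar1 < 1.0:
            raise ValueError("noise_ar1 must lie in [0, 1)")
        if not (lo <= self.base_level <= hi):
            raise ValueError("base_level must lie inside value_band")


@dataclass(frozen=True)
class CovariateConfig:
    """Target correlations and noise levels for the covariate channels.

    ``noise_sd`` optionally adds white measurement noise per channel (in the
    channel's physical units, after rescaling); it slightly lowers the
    realized correlation below the target.
    """

    target_correlations: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_CORRELATIONS)
    )
    noise_sd: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, rho in self.target_correlations.items():
            if not abs(rho) < 1.0:
                raise ValueError(f"|rho| must be < 1 for channel {name!r}")
        for name, sd in self.noise_sd.items():
            if sd < 0:
                raise ValueError(f"noise_sd must be >= 0 for channel {name!r}")


def simulate_stem_moisture(config: SimulationConfig) -> Series:
    """Generate a fully observed diurnal stem-moisture series.

    signal = base + diurnal sinusoid (period = samples_per_day, seeded random
    phase) + slow random-walk trend + AR(1) Gaussian noise, clipped to
    ``value_band``.  Identical config (including seed) gives identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_days * config.samples_per_day
    t = np.arange(n)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    signal = config.base_level + config.diurnal_amplitude * np.sin(
        2.0 * np.pi * t / config.samples_per_day + phase
    )
    if config.trend_amplitude > 0:
        # smooth trend: cumulative Gaussian walk rescaled to the requested amplitude
        walk = np.cumsum(rng.standard_normal(n))
        span = np.abs(walk).max()
        if span > 0:
            signal = signal + config.trend_amplitude * walk / span
    if config.noise_sd > 0:
        eps = rng.standard_normal(n) * config.noise_sd * np.sqrt(1.0 - config.noise_ar1**2)
        noise = np.empty(n)
        noise[0] = rng.standard_normal() * config.noise_sd
        for i in range(1, n):
            noise[i] = config.noise_ar1 * noise[i - 1] + eps[i]
        signal = signal + noise
    lo, hi = config.value_band
    n_clipped = int(((signal < lo) | (signal > hi)).sum())
    if n_clipped > 0.01 * n:
        warnings.warn(
            f"{n_clipped}/{n} points clipped to the value band; "
            "consider reducing amplitudes or noise",
            stacklevel=2,
        )
    return Series(values=np.clip(signal, lo, hi), mask=np.zeros(n, dtype=bool))


def simulate_covariates(
    target: Series, config: CovariateConfig | None = None
) -> dict[str, Series]:
    """Generate covariate channels with prescribed correlation to *target*.

    Each channel is ``rho * standardized(target) + sqrt(1 - rho²) * noise``
    rescaled to a plausible physical range (air humidity clipped to 0–100 %,
    PAR rectified at 0).  For series of length ≥ 5000 the empirical Pearson
    correlation lands within about ±0.05 of the requested value; rectification
    of PAR distorts it slightly.
    """
    if target.mask.any():
        raise ValueError("target series must be fully observed")
    config = config or CovariateConfig()
    rng = np.random.default_rng(config.seed)
    z = target.values - target.values.mean()
    sd = z.std()
    if sd == 0:
        raise ValueError("constant target: correlation undefined")
    z = z / sd
    n = len(target)
    out: dict[str, Series] = {}
    for name, rho in config.target_correlations.items():
        noise = rng.standard_normal(n)
        noise = (noise - noise.mean()) / noise.std()
        shaped = rho * z + np.sqrt(1.0 - rho**2) * noise
        mean, scale, lo, hi = _COVARIATE_SCALES.get(name, (0.0, 1.0, None, None))
        physical = mean + scale * shaped
        extra_sd = config.noise_sd.get(name, 0.0)
        if extra_sd > 0:
            physical = physical + extra_sd * rng.standard_normal(n)
        if lo is not None or hi is not None:
            physical = np.clip(physical, lo, hi)
        out[name] = Series(
            values=physical,
            mask=np.zeros(n, dtype=bool),
            start_time=target.start_time,
            cadence=target.cadence,
            channel_name=name,
        )
    return out


#: named benchmark layouts: (total length, gap length) with the gap centered
#: so the flanks keep a 5:1 train:test ratio on each side
SCENARIOS = {
    "paper-small": (2200, 200),
    "paper-large": (11000, 1000),
}


def make_benchmark_scenario(
    name: str,
    seed: int,
    *,
    total_length: int | None = None,
    gap_length: int | None = None,
) -> tuple[Series, GapSpec, dict[str, Series]]:
    """Build a named benchmark: truth series, centered gap, and covariates.

    ``paper-small`` is 2200 points with a 200-long centered gap (1000
    observed on each side); ``paper-large`` is 11000 points with a 1000-long
    centered gap (5000 per side).  ``custom`` requires *total_length* and
    *gap_length*.  Returns the fully observed truth, the GapSpec and the
    covariate channels; callers mask the gap themselves (see
    :func:`stemfill.core_series.mask_gap`).
    """
    if name in SCENARIOS:
        total, gap_len = SCENARIOS[name]
    elif name == "custom":
        if total_length is None or gap_length is None:
            raise ValueError("custom scenario requires total_length and gap_length")
        total, gap_len = total_length, gap_length
    else:
        raise ValueError(f"unknown scenario {name!r}")
    samples_per_day = 144
    n_days = -(-total // samples_per_day)  # ceil
    sim = SimulationConfig(n_days=n_days, seed=seed)
    truth_full = simulate_stem_moisture(sim)
    truth = Series(
        values=truth_full.values[:total],
        mask=np.zeros(total, dtype=bool),
        start_time=truth_full.start_time,
        cadence=truth_full.cadence,
    )
    gap = GapSpec(start=(total - gap_len) // 2, length=gap_len)
    covariates = simulate_covariates(truth, CovariateConfig(seed=seed + 1))
    return truth, gap, covariates


def masked_scenario(name: str, seed: int, **kwargs):
    """Convenience: like :func:`make_benchmark_scenario` but also returns the
    masked copy of the truth."""
    truth, gap, covariates = make_benchmark_scenario(name, seed, **kwargs)
    return truth, mask_gap(truth, gap), gap, covariates
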