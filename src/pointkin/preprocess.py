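"""Position filtering and velocity estimation.

Raw tracker streams are low-pass filtered at 15 Hz with a sixth-order
Butterworth filter before any kinematic quantity is derived.  By default
the filter is applied forward and backward (zero phase) so that phase
boundary timestamps are not biased by filter lag; the effective amplitude
response is then the squared single-pass magnitude.  Velocities come from
central differences on the filtered positions; phase segmentation uses the
speed component in the sagittal (yz) plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .trajectory import TooShortError, TrajectorySeries


@dataclass(frozen=True)
class FilterConfig:
    """Butterworth low-pass settings.

    cutoff: corner frequency in Hz (must sit below Nyquist).
    order: filter order; must be even and >= 2.
    zero_phase: apply forward-backward (no lag, squared attenuation) when
        True, single forward pass otherwise.
    """

    cutoff: float = 15.0
    order: int = 6
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.order < 2 or self.order % 2:
            raise ValueError("order must be even and >= 2")


def lowpass_filter(series: TrajectorySeries, cfg: FilterConfig = FilterConfig()) -> TrajectorySeries:
    """Low-pass filter each position axis independently.

    The series is padded by reflection with ``3 * order`` samples on each
    side before filtering, so short warm-up transients do not leak into the
    trial.  Event marks and sample times are untouched.
    """
    nyquist = series.sampling_rate / 2.0
    if cfg.cutoff >= nyquist:
        raise ValueError(
            f"cutoff {cfg.cutoff} Hz must be below Nyquist ({nyquist} Hz)"
        )
    pad = 3 * cfg.order
    if series.n_samples < pad:
        raise TooShortError(
            f"need at least {pad} samples to filter, got {series.n_samples}"
        )
    sos = signal.butter(cfg.order, cfg.cutoff, fs=series.sampling_rate, output="sos")
    padded = np.pad(series.position, ((pad, pad), (0, 0)), mode="reflect")
    if cfg.zero_phase:
        out = signal.sosfiltfilt(sos, padded, axis=0, padlen=0)
    else:
        out = signal.sosfilt(sos, padded, axis=0)
    return series.with_position(out[pad:-pad])


@dataclass
class Velocity:
    """Per-sample velocity estimates derived from a (filtered) series.

    velocity: ``(n, 3)`` signed axis velocities in m/s.
    speed: full 3D speed in m/s.
    sagittal_speed: speed in the yz (depth-altitude) plane, the quantity
        the movement-phase detector thresholds.
    """

    velocity: np.ndarray
    speed: np.ndarray
    sagittal_speed: np.ndarray


def compute_velocity(series: TrajectorySeries) -> Velocity:
    """Velocity via central differences (one-sided at the ends)."""
    if series.n_samples < 3:
        raise TooShortError("need at least 3 samples to differentiate")
    v = np.gradient(series.position, series.time, axis=0)
    speed = np.linalg.norm(v, axis=1)
    sagittal = np.hypot(v[:, 1], v[:, 2])
    return Velocity(velocity=v, speed=speed, sagittal_speed=sagittal)
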