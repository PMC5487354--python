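"""Movement-phase segmentation by speed threshold and spatial gates.

Each trial decomposes into four phases: *reaction* (stimulus to home-key
release), *forward* transport (sagittal speed above threshold while moving
from home to the signs), *hold* (speed below threshold in proximity of the
signs), and *backward* transport (speed above threshold again, returning to
the home-key).  Onsets and offsets combine a 0.1 m/s sagittal-speed
threshold with spatial gates around the home-key and the sign row; trials
whose detected phases violate the gates are flagged, not discarded here —
exclusion happens downstream.

Conventions (documented because the threshold rule is convention
sensitive): a phase onset is the first sample strictly above threshold, the
offset is the first sample back below it (half-open interval); "remained
above" is operationalized as a debounce window (default 50 ms) so
noise-induced micro-crossings do not spawn phases; gate boundaries are
inclusive ("no more than" means <=).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import Velocity, compute_velocity
from .trajectory import TrajectorySeries

#: reason codes attached to invalid trials
NO_MOVEMENT = "no movement detected"
START_OUTSIDE_GATE = "start outside gate"
HOLD_OUTSIDE_PROXIMITY = "hold outside sign proximity"
NO_HOLD = "no holding phase detected"
NO_BACKWARD = "no backward movement detected"
BACKWARD_END_OUTSIDE_GATE = "backward end outside gate"


@dataclass(frozen=True)
class GateSpec:
    """Spatial gates, meters.

    The forward movement must start no more than ``start_max_above`` above
    and ``start_max_forward`` in front of the home-key, and end no more
    than ``end_max_above`` above, ``end_max_below`` below, or
    ``end_max_lateral`` left/right of the signs.  The same limits apply to
    the backward movement with start/end roles swapped.
    """

    start_max_above: float = 0.10
    start_max_forward: float = 0.08
    end_max_above: float = 0.10
    end_max_below: float = 0.15
    end_max_lateral: float = 0.15

    def __post_init__(self) -> None:
        for name in (
            "start_max_above",
            "start_max_forward",
            "end_max_above",
            "end_max_below",
            "end_max_lateral",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class SegmentationConfig:
    speed_threshold: float = 0.1  # m/s, on sagittal (yz) speed
    min_supra_duration_ms: float = 50.0  # debounce for "remained above"
    min_hold_duration_ms: float = 12.0  # 3 samples at 250 Hz
    gates: GateSpec = field(default_factory=GateSpec)
    release_fallback_distance: float = 0.005  # m, used when no event mark
    # sub-sample refinement of the threshold crossings: a local quadratic
    # fit of the speed around the provisional crossing, re-centered once;
    # averages sensor noise over the window instead of trusting one sample
    refine_crossings: bool = True
    refine_halfwidth_ms: float = 80.0
    refine_iterations: int = 2

    def __post_init__(self) -> None:
        if self.speed_threshold <= 0:
            raise ValueError("speed_threshold must be positive")
        if self.min_supra_duration_ms < 0 or self.min_hold_duration_ms < 0:
            raise ValueError("durations must be non-negative")


@dataclass(frozen=True)
class TaskGeometry:
    """Home-key and sign positions in the task frame (meters)."""

    home: tuple[float, float, float] = (0.0, 0.0, 0.0)
    signs: tuple[tuple[float, float, float], ...] = (
        (-0.046, 0.485, 0.024),
        (-0.001, 0.505, 0.032),
        (0.046, 0.522, 0.036),
    )

    def __post_init__(self) -> None:
        xs = [s[0] for s in self.signs]
        if not all(a < b for a, b in zip(xs, xs[1:])):
            raise ValueError("sign x-coordinates must increase left to right")

    @property
    def home_arr(self) -> np.ndarray:
        return np.asarray(self.home, dtype=float)

    @property
    def signs_arr(self) -> np.ndarray:
        return np.asarray(self.signs, dtype=float)


@dataclass
class PhaseBounds:
    """Per-trial phase onsets/offsets (seconds) and validity flags.

    Durations are derived properties in milliseconds.  ``valid`` is False
    when any reason code is present; invalid trials keep whatever bounds
    could be estimated (NaN otherwise).
    """

    t_stimulus: float = np.nan
    t_release: float = np.nan
    forward_onset: float = np.nan
    forward_offset: float = np.nan
    hold_onset: float = np.nan
    hold_offset: float = np.nan
    backward_onset: float = np.nan
    backward_offset: float = np.nan
    reasons: tuple[str, ...] = ()

    @property
    def valid(self) -> bool:
        return not self.reasons

    @property
    def rtc_ms(self) -> float:
        return 1e3 * (self.t_release - self.t_stimulus)

    @property
    def mtf_ms(self) -> float:
        return 1e3 * (self.forward_offset - self.forward_onset)

    @property
    def ht_ms(self) -> float:
        return 1e3 * (self.hold_offset - self.hold_onset)

    @property
    def mtb_ms(self) -> float:
        return 1e3 * (self.backward_offset - self.backward_onset)

    def as_dict(self) -> dict:
        return {
            "t_stimulus": self.t_stimulus,
            "t_release": self.t_release,
            "forward_onset": self.forward_onset,
            "forward_offset": self.forward_offset,
            "hold_onset": self.hold_onset,
            "hold_offset": self.hold_offset,
            "backward_onset": self.backward_onset,
            "backward_offset": self.backward_offset,
            "rtc_ms": self.rtc_ms,
            "mtf_ms": self.mtf_ms,
            "ht_ms": self.ht_ms,
            "mtb_ms": self.mtb_ms,
            "valid": self.valid,
            "reasons": ";".join(self.reasons),
        }


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index spans of consecutive True samples."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def _refine_crossing(
    t: np.ndarray,
    speed: np.ndarray,
    i_after: int,
    cfg: SegmentationConfig,
) -> float:
    """Sub-sample estimate of a speed-threshold crossing.

    ``i_after`` is the first sample on the far side of the crossing.  A
    quadratic is fit to the speed within ``refine_halfwidth_ms`` of the
    provisional crossing (the midpoint of the bracketing samples) and its
    root nearest the center is taken; the window is re-centered and the
    fit repeated.  Falls back to the provisional midpoint when the fit has
    no root in the window.
    """
    if not cfg.refine_crossings:
        return float(t[i_after])
    dt = t[1] - t[0] if t.size > 1 else 0.0
    tc = float(t[i_after]) - 0.5 * dt
    half_w = cfg.refine_halfwidth_ms / 1e3
    for _ in range(max(1, cfg.refine_iterations)):
        m = (t >= tc - half_w) & (t <= tc + half_w)
        if m.sum() < 5:
            return tc
        coef = np.polyfit(t[m] - tc, speed[m] - cfg.speed_threshold, 2)
        roots = np.roots(coef)
        roots = roots[np.isreal(roots)].real
        roots = roots[np.abs(roots) <= half_w]
        if roots.size == 0:
            return tc
        tc = tc + float(roots[np.argmin(np.abs(roots))])
    return tc


def _in_sign_proximity(p: np.ndarray, geometry: TaskGeometry, gates: GateSpec) -> bool:
    signs = geometry.signs_arr
    x_ok = (p[0] >= signs[:, 0].min() - gates.end_max_lateral) and (
        p[0] <= signs[:, 0].max() + gates.end_max_lateral
    )
    z_ok = (p[2] >= signs[:, 2].min() - gates.end_max_below) and (
        p[2] <= signs[:, 2].max() + gates.end_max_above
    )
    return bool(x_ok and z_ok)


def _near_home(p: np.ndarray, geometry: TaskGeometry, gates: GateSpec) -> bool:
    home = geometry.home_arr
    return bool(
        (p[2] - home[2]) <= gates.start_max_above
        and (p[1] - home[1]) <= gates.start_max_forward
    )


def segment_trial(
    series: TrajectorySeries,
    cfg: SegmentationConfig = SegmentationConfig(),
    geometry: TaskGeometry = TaskGeometry(),
    velocity: Velocity | None = None,
) -> PhaseBounds:
    """Decompose one (filtered) trial into movement phases.

    Parameters
    ----------
    series:
        Filtered trajectory with at least a ``stimulus`` event mark.
    velocity:
        Optional precomputed :class:`Velocity`; derived from ``series``
        when omitted.

    Returns
    -------
    PhaseBounds with durations and validity flags.  A trial with no
    supra-threshold movement is returned flagged (``no movement
    detected``), not raised.
    """
    if "stimulus" not in series.events:
        raise ValueError("series lacks the required 'stimulus' event mark")
    vel = velocity if velocity is not None else compute_velocity(series)
    t = series.time
    dt = series.dt
    thr = cfg.speed_threshold

    bounds = PhaseBounds(t_stimulus=float(series.events["stimulus"]))
    reasons: list[str] = []

    # --- movement initiation (home-key release)
    if "home_release" in series.events:
        bounds.t_release = float(series.events["home_release"])
    else:
        dist = np.linalg.norm(series.position - geometry.home_arr, axis=1)
        away = np.flatnonzero(dist > cfg.release_fallback_distance)
        bounds.t_release = float(t[away[0]]) if away.size else np.nan

    supra = vel.sagittal_speed > thr
    min_supra_n = max(1, int(round(cfg.min_supra_duration_ms / 1e3 / dt)))
    min_hold_n = max(1, int(round(cfg.min_hold_duration_ms / 1e3 / dt)))
    supra_runs = [r for r in _runs(supra) if (r[1] - r[0]) >= min_supra_n]

    i_release = series.index_at(bounds.t_release) if np.isfinite(bounds.t_release) else 0
    fwd_runs = [r for r in supra_runs if r[1] > i_release]
    if not fwd_runs:
        bounds.reasons = (NO_MOVEMENT,)
        return bounds

    sp = vel.sagittal_speed
    f0, f1 = fwd_runs[0]
    bounds.forward_onset = _refine_crossing(t, sp, f0, cfg) if f0 > 0 else float(t[0])
    bounds.forward_offset = (
        _refine_crossing(t, sp, f1, cfg) if f1 < t.size else float(t[-1])
    )

    # --- hold: longest sub-threshold interval near the signs after forward
    # the end-point hold sits between forward and backward transport, so a
    # qualifying run may not extend to the end of the recording (that final
    # sub-threshold stretch is the post-return rest at the home-key)
    sub_runs = [
        r
        for r in _runs(~supra)
        if r[0] >= f1 and r[1] < supra.size and (r[1] - r[0]) >= min_hold_n
    ]
    qualifying = []
    for r in sub_runs:
        center = np.median(series.position[r[0] : r[1]], axis=0)
        if _in_sign_proximity(center, geometry, cfg.gates):
            qualifying.append(r)
    hold_run = None
    if qualifying:
        hold_run = max(qualifying, key=lambda r: (r[1] - r[0], -r[0]))
    elif sub_runs:
        hold_run = sub_runs[0]
        reasons.append(HOLD_OUTSIDE_PROXIMITY)
    else:
        reasons.append(NO_HOLD)

    if hold_run is not None:
        h0, h1 = hold_run
        # contiguous with the forward run, the hold onset is the same
        # crossing as the forward offset (half-open phase convention)
        bounds.hold_onset = (
            bounds.forward_offset if h0 == f1 else _refine_crossing(t, sp, h0, cfg)
        )
        bounds.hold_offset = (
            _refine_crossing(t, sp, h1, cfg) if h1 < t.size else float(t[-1])
        )

        # --- backward: first supra run after the hold, ending near home
        bwd_runs = [r for r in supra_runs if r[0] >= h1]
        if bwd_runs:
            b0, b1 = bwd_runs[0]
            bounds.backward_onset = (
                bounds.hold_offset if b0 == h1 else _refine_crossing(t, sp, b0, cfg)
            )
            bounds.backward_offset = (
                _refine_crossing(t, sp, b1, cfg) if b1 < t.size else float(t[-1])
            )
        else:
            reasons.append(NO_BACKWARD)

    reasons.extend(validate_gates(bounds, series, geometry, cfg.gates))
    bounds.reasons = tuple(dict.fromkeys(reasons))  # dedupe, keep order
    return bounds


def validate_gates(
    bounds: PhaseBounds,
    series: TrajectorySeries,
    geometry: TaskGeometry = TaskGeometry(),
    gates: GateSpec = GateSpec(),
) -> list[str]:
    """Check phase start/end positions against the spatial gates.

    Pure function: returns a list of reason codes (empty when all gates
    pass).  Checks the forward start against the home gate, the hold
    position against the sign-proximity gate, and the backward end against
    the home gate.
    """
    reasons: list[str] = []
    if np.isfinite(bounds.forward_onset):
        p = series.position[series.index_at(bounds.forward_onset)]
        if not _near_home(p, geometry, gates):
            reasons.append(START_OUTSIDE_GATE)
    if np.isfinite(bounds.hold_onset) and np.isfinite(bounds.hold_offset):
        i0 = series.index_at(bounds.hold_onset)
        i1 = max(i0 + 1, series.index_at(bounds.hold_offset))
        center = np.median(series.position[i0:i1], axis=0)
        if not _in_sign_proximity(center, geometry, gates):
            reasons.append(HOLD_OUTSIDE_PROXIMITY)
    if np.isfinite(bounds.backward_offset):
        i = min(series.index_at(bounds.backward_offset), series.n_samples - 1)
        if not _near_home(series.position[i], geometry, gates):
            reasons.append(BACKWARD_END_OUTSIDE_GATE)
    return reasons
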