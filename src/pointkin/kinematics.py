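"""Per-trial kinematic parameters and time-normalized trajectory profiles.

Scalar parameters per trial: phase durations (RTc, MTf, HT, MTb, MTa),
forward trajectory length TL (cm), peak velocity PV (cm/s), relative
time-to-peak-velocity rtPV (% of forward movement time), and the
end-point position EPx/EPy/EPz (mm, in a configurable reporting frame).
Forward trajectories are additionally resampled to 100 time-equidistant
samples by cubic-spline interpolation, with the spline's analytic
derivative providing signed instantaneous axis velocities — the basis of
the lateral-development analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .preprocess import Velocity, compute_velocity
from .segmentation import PhaseBounds
from .trajectory import TooShortError, TrajectorySeries

N_PROFILE_SAMPLES = 100


class MissingCellError(ValueError):
    """A required design cell has no trials."""


@dataclass(frozen=True)
class ReportingFrame:
    """Origin (meters, task frame) of the end-point reporting frame.

    End-points are expressed in millimeters rightward/forward/upward of
    this origin.  The default places x-zero 18 mm left of the default left
    sign so sign end-points land on the familiar lateral scale
    (roughly 18 / 63 / 110 mm for left / middle / right).
    """

    origin: tuple[float, float, float] = (-0.064, 0.47, 0.0)

    def to_mm(self, p: np.ndarray) -> np.ndarray:
        return (np.asarray(p, dtype=float) - np.asarray(self.origin)) * 1e3


@dataclass
class KinematicSummary:
    """Scalar kinematic parameters for one trial (NaN when unavailable)."""

    rtc_ms: float = np.nan
    mtf_ms: float = np.nan
    ht_ms: float = np.nan
    mtb_ms: float = np.nan
    mta_ms: float = np.nan
    tl_cm: float = np.nan
    pv_cms: float = np.nan
    rtpv_pct: float = np.nan
    epx_mm: float = np.nan
    epy_mm: float = np.nan
    epz_mm: float = np.nan
    valid: bool = True
    reasons: tuple[str, ...] = ()

    #: parameter column names, in reporting order
    PARAMS = (
        "rtc_ms",
        "mtf_ms",
        "ht_ms",
        "mtb_ms",
        "mta_ms",
        "tl_cm",
        "pv_cms",
        "rtpv_pct",
        "epx_mm",
        "epy_mm",
        "epz_mm",
    )

    def as_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self) if f.name != "reasons"}
        d["reasons"] = ";".join(self.reasons)
        return d


def extract_parameters(
    series: TrajectorySeries,
    bounds: PhaseBounds,
    frame: ReportingFrame = ReportingFrame(),
    velocity: Velocity | None = None,
    endpoint_from_hold_mean: bool = False,
) -> KinematicSummary:
    """Extract scalar parameters for one segmented trial.

    Invalid bounds are not an exception: the summary is returned with NaN
    parameters and the segmentation reason codes propagated, so the
    exclusion stage can count the trial under the right rule.

    PV is the full 3D speed maximum inside the forward phase (the sagittal
    projection is a segmentation device, not a reported parameter); the
    end-point is the position at forward-phase offset, or the hold-phase
    mean when ``endpoint_from_hold_mean`` is set.
    """
    if not bounds.valid:
        return KinematicSummary(
            rtc_ms=bounds.rtc_ms,
            valid=False,
            reasons=bounds.reasons,
        )
    vel = velocity if velocity is not None else compute_velocity(series)
    i0 = series.index_at(bounds.forward_onset)
    i1 = series.index_at(bounds.forward_offset)
    if i1 - i0 < 2:
        return KinematicSummary(valid=False, reasons=("forward phase too short",))

    pos = series.position[i0 : i1 + 1]
    tl_cm = float(np.sum(np.linalg.norm(np.diff(pos, axis=0), axis=1)) * 1e2)

    speed = vel.speed[i0 : i1 + 1]
    k = int(np.argmax(speed))
    pv_cms = float(speed[k] * 1e2)
    rtpv_pct = float(
        100.0
        * (series.time[i0 + k] - bounds.forward_onset)
        / (bounds.forward_offset - bounds.forward_onset)
    )

    if endpoint_from_hold_mean and np.isfinite(bounds.hold_offset):
        h0 = series.index_at(bounds.hold_onset)
        h1 = max(h0 + 1, series.index_at(bounds.hold_offset))
        ep = frame.to_mm(series.position[h0:h1].mean(axis=0))
    else:
        ep = frame.to_mm(series.position[i1])

    mta = np.nan
    ev = series.events
    if "addressee_release" in ev and "addressee_select" in ev:
        mta = 1e3 * (ev["addressee_select"] - ev["addressee_release"])

    return KinematicSummary(
        rtc_ms=bounds.rtc_ms,
        mtf_ms=bounds.mtf_ms,
        ht_ms=bounds.ht_ms,
        mtb_ms=bounds.mtb_ms,
        mta_ms=float(mta),
        tl_cm=tl_cm,
        pv_cms=pv_cms,
        rtpv_pct=rtpv_pct,
        epx_mm=float(ep[0]),
        epy_mm=float(ep[1]),
        epz_mm=float(ep[2]),
    )


@dataclass
class NormalizedTrajectory:
    """Forward trajectory resampled at 100 time-equidistant samples.

    tau: normalized time in [0, 1] (100 points).
    position: ``(100, 3)`` meters.
    velocity: ``(100, 3)`` signed instantaneous derivative, m/s.
    """

    tau: np.ndarray
    position: np.ndarray
    velocity: np.ndarray


def time_normalize(
    series: TrajectorySeries,
    bounds: PhaseBounds,
    n_samples: int = N_PROFILE_SAMPLES,
) -> NormalizedTrajectory:
    """Resample the forward phase at equally spaced times via cubic spline.

    A natural cubic spline is fit through the forward-phase samples (one
    neighbor each side included for end-condition stability) and evaluated,
    together with its analytic first derivative, at ``n_samples`` equally
    spaced times between forward onset and offset.
    """
    i0 = series.index_at(bounds.forward_onset)
    i1 = series.index_at(bounds.forward_offset)
    lo = max(0, i0 - 1)
    hi = min(series.n_samples, i1 + 2)
    if hi - lo < 4:
        raise TooShortError("forward phase must span at least 4 samples")
    cs = CubicSpline(series.time[lo:hi], series.position[lo:hi], axis=0)
    grid = np.linspace(bounds.forward_onset, bounds.forward_offset, n_samples)
    return NormalizedTrajectory(
        tau=np.linspace(0.0, 1.0, n_samples),
        position=cs(grid),
        velocity=cs.derivative()(grid),
    )


@dataclass
class LateralContrast:
    """Condition-cell means and mind-minus-object differences of lateral
    (x-axis) displacement/velocity profiles.

    ``cell_position`` / ``cell_velocity`` are DataFrames indexed by
    (subject, action, addressee, sign) with one column per normalized time
    sample.
    """

    cell_position: pd.DataFrame
    cell_velocity: pd.DataFrame

    def _cells(self, which: str) -> pd.DataFrame:
        return self.cell_position if which == "position" else self.cell_velocity

    def grand_mean(self, which: str = "position", **levels) -> np.ndarray:
        """Grand-mean profile over subjects for the selected condition(s)."""
        df = self._cells(which)
        for name, value in levels.items():
            df = df.xs(value, level=name, drop_level=False)
        return df.groupby(level="subject").mean().mean(axis=0).to_numpy()

    def action_difference(
        self, by: str = "sign", which: str = "position"
    ) -> pd.DataFrame:
        """Mind-minus-object mean profiles split by ``by`` (sign or addressee)."""
        df = self._cells(which)
        subj = df.groupby(level=["subject", "action", by]).mean()
        mind = subj.xs("mind", level="action")
        obj = subj.xs("object", level="action")
        return (mind - obj).groupby(level=by).mean()

    def subject_action_difference(
        self, which: str = "position", select: dict | None = None
    ) -> np.ndarray:
        """Per-subject mind-minus-object profile matrix ``(n_subjects, n_samples)``.

        ``select`` optionally restricts cells first, e.g. ``{"sign": ["left",
        "right"]}`` to pool the outer signs.
        """
        df = self._cells(which)
        if select:
            for name, values in select.items():
                values = [values] if isinstance(values, str) else list(values)
                df = df[df.index.get_level_values(name).isin(values)]
        subj = df.groupby(level=["subject", "action"]).mean()
        mind = subj.xs("mind", level="action")
        obj = subj.xs("object", level="action")
        return (mind - obj).sort_index().to_numpy()


def lateral_contrast(
    labels: pd.DataFrame,
    position: np.ndarray,
    velocity: np.ndarray | None = None,
) -> LateralContrast:
    """Aggregate per-trial lateral profiles into condition-cell means.

    Parameters
    ----------
    labels:
        One row per trial with columns ``subject``, ``action``,
        ``addressee``, ``sign``.
    position, velocity:
        ``(n_trials, n_samples)`` lateral displacement / signed lateral
        velocity matrices aligned with ``labels`` rows.

    Raises
    ------
    MissingCellError
        naming the first empty (subject, action, addressee, sign) cell.
    """
    required = ["subject", "action", "addressee", "sign"]
    position = np.asarray(position, dtype=float)
    if velocity is None:
        velocity = np.full_like(position, np.nan)
    idx = pd.MultiIndex.from_frame(labels[required])
    pos = pd.DataFrame(position, index=idx)
    vel = pd.DataFrame(np.asarray(velocity, dtype=float), index=idx)

    cell_pos = pos.groupby(level=required).mean()
    cell_vel = vel.groupby(level=required).mean()

    subjects = labels["subject"].unique()
    full = pd.MultiIndex.from_product(
        [subjects, ["mind", "object"], ["left", "right"], ["left", "middle", "right"]],
        names=required,
    )
    missing = full.difference(cell_pos.index)
    if len(missing):
        raise MissingCellError(f"no trials in cell {tuple(missing[0])}")
    return LateralContrast(
        cell_position=cell_pos.reindex(full), cell_velocity=cell_vel.reindex(full)
    )
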