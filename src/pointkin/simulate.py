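"""Synthetic pointing experiments with known ground truth.

Generates complete 2 (action: mind/object) x 2 (addressee: left/right) x 3
(sign: left/middle/right) pointing experiments: 240 trials per subject in
24 blocks of ten, with the addressee side alternating every block and the
action condition every two blocks.  Each trial is a forward-hold-backward
index-finger stream sampled at 250 Hz: a stationary reaction segment, a
minimum-jerk reach to the selected sign, a stationary hold, and a
minimum-jerk return to the home-key, followed by additive Gaussian sensor
noise and quantization to the tracker resolution.

Condition effects are superposed as smooth, differentiable lateral bias
fields so the forward kinematics stay minimum-jerk in the sagittal plane:

* holding-time prolongation on mind trials (largest toward the middle
  sign), reaction-time and backward-time prolongation on mind trials;
* end-point shifts toward the addressee, and outward end-point shifts for
  the outer signs on mind trials;
* an early lateral trajectory shift (a bump active from 10% of normalized
  movement time) on mind trials;
* a late addressee-directed lateral displacement ramping in over the final
  quarter of the movement (its derivative is the late addressee-directed
  lateral-velocity effect).

Reaction and holding times are log-normal (positive, right-skewed);
transport times are truncated normal.  Ground truth is recorded before
noise: both the kinematic segment boundaries and the analytic 0.1 m/s
sagittal-speed threshold crossings an ideal detector would report.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .kinematics import KinematicSummary, ReportingFrame
from .segmentation import PhaseBounds, TaskGeometry
from .trajectory import TrajectorySeries, write_trajectories

ACTIONS = ("mind", "object")
ADDRESSEES = ("left", "right")
SIGNS = ("left", "middle", "right")

_SIGN_DIR = {"left": -1.0, "middle": 0.0, "right": 1.0}
_ADDR_DIR = {"left": -1.0, "right": 1.0}


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignSpec:
    """Structure of the experiment (sizes, rates, geometry)."""

    n_subjects: int = 13
    n_trials_total: int = 240
    block_size: int = 10
    sampling_rate: float = 250.0
    geometry: TaskGeometry = field(default_factory=TaskGeometry)
    addressee_positions: tuple[tuple[float, float, float], ...] = (
        (-0.45, 0.35, 0.0),
        (0.45, 0.35, 0.0),
    )
    reporting_frame: ReportingFrame = field(default_factory=ReportingFrame)
    pre_stimulus_s: float = 0.2
    tail_s: float = 0.3

    def __post_init__(self) -> None:
        if self.n_trials_total <= 0:
            raise ValueError("n_trials_total must be positive")
        if self.n_trials_total % self.block_size:
            raise ValueError("n_trials_total must be divisible by block_size")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_blocks(self) -> int:
        return self.n_trials_total // self.block_size


@dataclass(frozen=True)
class EffectSpec:
    """Injected condition effects and variability (ms / mm).

    Duration defaults reproduce the target condition means: reaction time
    1945 ms (+98 on mind trials), holding time 227 ms for object trials
    (+185 on mind trials, +48 more toward the middle sign, so the
    mind/object pair at the middle sign means 460 vs 227 ms and the action
    main effect is 201 ms), backward time 704 ms (+45 on mind).  Spatial
    defaults: 0.25 mm end-point shift toward the addressee on every trial,
    2.4 mm outward end-point shift for the outer signs on mind trials, a
    2 mm early lateral shift (active from 10% of movement) on mind trials,
    and 0.6 mm of late addressee-directed displacement ramping in over the
    final quarter on mind trials.
    """

    rt_base: float = 1945.0
    rt_mind_delta: float = 98.0
    mtf_base: float = 870.0
    ht_base_object: float = 227.0
    ht_mind_delta: float = 185.0
    ht_mind_middle_extra: float = 48.0
    mtb_base: float = 704.0
    mtb_mind_delta: float = 45.0
    mta_base_by_sign: tuple[float, float, float] = (1403.0, 1355.0, 1322.0)

    endpoint_addressee_shift_mm: float = 0.25
    endpoint_mind_outward_shift_mm: float = 2.4
    early_lateral_shift_mm: float = 2.0
    late_addressee_shift_mm: float = 0.6

    # between-subject (offset drawn once per subject) and trial-to-trial sds
    rt_subject_sd: float = 350.0
    rt_trial_sd: float = 380.0
    mtf_subject_sd: float = 110.0
    mtf_trial_sd: float = 60.0
    ht_subject_sd: float = 60.0
    ht_trial_sd: float = 80.0
    mtb_subject_sd: float = 100.0
    mtb_trial_sd: float = 50.0
    mta_trial_sd: float = 150.0
    endpoint_trial_sd_mm: float = 2.5

    # independent error-injection rates (communicator / addressee / both)
    p_communicator_error: float = 0.019
    p_addressee_error: float = 0.027
    p_both_error: float = 0.030

    def __post_init__(self) -> None:
        for name in ("rt_base", "mtf_base", "ht_base_object", "mtb_base"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def null(cls) -> "EffectSpec":
        """All condition deltas and variability zeroed (for oracle tests)."""
        return cls(
            rt_mind_delta=0.0,
            ht_mind_delta=0.0,
            ht_mind_middle_extra=0.0,
            mtb_mind_delta=0.0,
            endpoint_addressee_shift_mm=0.0,
            endpoint_mind_outward_shift_mm=0.0,
            early_lateral_shift_mm=0.0,
            late_addressee_shift_mm=0.0,
            rt_subject_sd=0.0,
            rt_trial_sd=0.0,
            mtf_subject_sd=0.0,
            mtf_trial_sd=0.0,
            ht_subject_sd=0.0,
            ht_trial_sd=0.0,
            mtb_subject_sd=0.0,
            mtb_trial_sd=0.0,
            mta_trial_sd=0.0,
            endpoint_trial_sd_mm=0.0,
            p_communicator_error=0.0,
            p_addressee_error=0.0,
            p_both_error=0.0,
        )


@dataclass(frozen=True)
class NoiseSpec:
    """Additive sensor noise (per axis) and quantization step, in mm."""

    position_noise_sd_mm: float = 0.3
    resolution_mm: float = 0.1

    def __post_init__(self) -> None:
        if self.position_noise_sd_mm < 0 or self.resolution_mm < 0:
            raise ValueError("noise parameters must be non-negative")

    @classmethod
    def zero(cls) -> "NoiseSpec":
        return cls(position_noise_sd_mm=0.0, resolution_mm=0.0)


@dataclass
class SubjectEffects:
    """Per-subject random offsets (ms), drawn once per subject."""

    rt: float = 0.0
    mtf: float = 0.0
    ht: float = 0.0
    mtb: float = 0.0


@dataclass
class SimulatedTrial:
    trial_id: str
    subject: int
    block: int
    trial_in_block: int
    action: str
    addressee: str
    sign: str
    series: TrajectorySeries
    truth_bounds: PhaseBounds
    truth: KinematicSummary
    communicator_correct: bool
    addressee_correct: bool


# ---------------------------------------------------------------------------
# Minimum-jerk primitives
# ---------------------------------------------------------------------------

def minimum_jerk_profile(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk position profile 10 tau^3 - 15 tau^4 + 6 tau^5."""
    return tau**3 * (10.0 - 15.0 * tau + 6.0 * tau**2)


def minimum_jerk_speed_profile(tau: np.ndarray) -> np.ndarray:
    """Derivative of the normalized profile: 30 tau^2 (1 - tau)^2."""
    return 30.0 * tau**2 * (1.0 - tau) ** 2


def minimum_jerk_trajectory(
    start, end, duration: float, sampling_rate: float
) -> TrajectorySeries:
    """Point-to-point minimum-jerk reach sampled at ``sampling_rate``.

    Starts at ``start``, ends at ``end``, with zero speed at both ends and
    peak speed 1.875 |end - start| / duration at mid-movement.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    n = int(np.floor(duration * sampling_rate)) + 1
    t = np.arange(n) / sampling_rate
    tau = np.clip(t / duration, 0.0, 1.0)
    pos = start + np.outer(minimum_jerk_profile(tau), end - start)
    return TrajectorySeries(time=t, position=pos, sampling_rate=sampling_rate)


def _smoothstep(tau: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Quintic smoothstep from 0 at ``lo`` to 1 at ``hi`` (zero end slopes)."""
    u = np.clip((tau - lo) / (hi - lo), 0.0, 1.0)
    return minimum_jerk_profile(u)


def _early_bump(tau: np.ndarray) -> np.ndarray:
    """Lateral bias bump: zero before 10% of movement, rising steeply to a
    plateau by 22% (the shift is present "already after 10%"), blending
    back into the end-point offset over the final third."""
    return _smoothstep(tau, 0.10, 0.22) * (1.0 - _smoothstep(tau, 0.70, 1.0))


def _late_ramp(tau: np.ndarray) -> np.ndarray:
    """Addressee-directed displacement ramping in over the final quarter."""
    return _smoothstep(tau, 0.75, 1.0)


def _lognormal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Log-normal draw parameterized by its mean and sd (ms scale)."""
    if sd <= 0:
        return mean
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def _positive_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd <= 0:
        return mean
    for _ in range(100):
        v = rng.normal(mean, sd)
        if v > 0.05 * mean:
            return float(v)
    return float(mean)


# ---------------------------------------------------------------------------
# Single-trial synthesis
# ---------------------------------------------------------------------------

def _threshold_crossings(d_sagittal: float, duration_s: float, threshold: float) -> tuple[float, float]:
    """Times (relative to segment start) where the sagittal speed of a
    minimum-jerk segment crosses the detector threshold."""
    peak = 1.875 * d_sagittal / duration_s
    if peak <= threshold:
        return (np.nan, np.nan)
    level = threshold * duration_s / d_sagittal

    def g(tau):
        return 30.0 * tau**2 * (1.0 - tau) ** 2 - level

    up = brentq(g, 1e-12, 0.5)
    down = brentq(g, 0.5, 1.0 - 1e-12)
    return (up * duration_s, down * duration_s)


def synthesize_trial(
    cell: tuple[str, str, str],
    effects: EffectSpec = EffectSpec(),
    noise: NoiseSpec = NoiseSpec(),
    design: DesignSpec = DesignSpec(),
    rng: np.random.Generator | int | None = 0,
    subject_effects: SubjectEffects | None = None,
    speed_threshold: float = 0.1,
) -> SimulatedTrial:
    """Generate one trial of the given design cell.

    ``cell`` is ``(action, addressee, sign)``.  The returned trial carries
    the noisy sampled trajectory plus noise-free ground truth: kinematic
    durations/end-point in ``truth`` and the analytic threshold-crossing
    phase bounds in ``truth_bounds``.  Generation is a pure function of
    the arguments and the seed.
    """
    action, addressee, sign = cell
    if action not in ACTIONS or addressee not in ADDRESSEES or sign not in SIGNS:
        raise ValueError(f"unknown design cell {cell!r}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    sub = subject_effects or SubjectEffects()
    mind = action == "mind"
    dir_s = _SIGN_DIR[sign]
    dir_a = _ADDR_DIR[addressee]
    sign_idx = SIGNS.index(sign)
    geom = design.geometry
    fs = design.sampling_rate

    # --- transport durations and spatial targets (ms -> s)
    rt_ms = _lognormal(rng, max(effects.rt_base + sub.rt + (effects.rt_mind_delta if mind else 0.0), 1.0), effects.rt_trial_sd)
    mtf_ms = _positive_normal(rng, max(effects.mtf_base + sub.mtf, 1.0), effects.mtf_trial_sd)
    mtb_ms = _positive_normal(rng, max(effects.mtb_base + sub.mtb + (effects.mtb_mind_delta if mind else 0.0), 1.0), effects.mtb_trial_sd)
    mta_ms = _positive_normal(rng, effects.mta_base_by_sign[sign_idx], effects.mta_trial_sd)
    rt, mtf, mtb = (v / 1e3 for v in (rt_ms, mtf_ms, mtb_ms))

    home = geom.home_arr
    target = geom.signs_arr[sign_idx].copy()
    target += rng.normal(0.0, effects.endpoint_trial_sd_mm * 1e-3, size=3)
    if mind:
        target[0] += dir_s * effects.endpoint_mind_outward_shift_mm * 1e-3
    early = (effects.early_lateral_shift_mm * 1e-3 * dir_s) if mind else 0.0
    # the addressee-directed displacement arrives late in the movement
    # (trajectories converge toward the addressee only near the end), so
    # the whole end-point shift rides on the final-quarter ramp
    late_mm = effects.endpoint_addressee_shift_mm + (
        effects.late_addressee_shift_mm if mind else 0.0
    )
    late = late_mm * 1e-3 * dir_a

    def forward_x(tau: np.ndarray) -> np.ndarray:
        base = home[0] + minimum_jerk_profile(tau) * (target[0] - home[0])
        return base + early * _early_bump(tau) + late * _late_ramp(tau)

    endpoint = target.copy()
    endpoint[0] = float(forward_x(np.array([1.0]))[0])

    # --- holding time.  The injected holding time is the *detected* hold —
    # the interval the sagittal speed stays below threshold — which
    # necessarily includes the transports' sub-threshold tails, so it has a
    # physical floor of (tail_f + tail_b).  Drawing the hold from a shifted
    # log-normal above that floor keeps its mean exactly at the injected
    # value, so condition contrasts are recovered without bias.
    d_sag = float(np.hypot(target[1] - home[1], target[2] - home[2]))
    f_up, f_down = _threshold_crossings(d_sag, mtf, speed_threshold)
    b_up, b_down = _threshold_crossings(d_sag, mtb, speed_threshold)
    tail_f = mtf - f_down if np.isfinite(f_down) else 0.0
    tail_b = b_up if np.isfinite(b_up) else 0.0
    floor_ms = (tail_f + tail_b) * 1e3 + 20.0
    ht_mean = effects.ht_base_object + sub.ht
    if mind:
        ht_mean += effects.ht_mind_delta
        if sign == "middle":
            ht_mean += effects.ht_mind_middle_extra
    ht_detected_ms = floor_ms + _lognormal(
        rng, max(ht_mean - floor_ms, 5.0), effects.ht_trial_sd
    )
    stationary_ht = ht_detected_ms / 1e3 - tail_f - tail_b

    # --- timeline
    lead = design.pre_stimulus_s
    t_stim = lead
    t_fwd = lead + rt
    t_hold = t_fwd + mtf
    t_bwd = t_hold + stationary_ht
    t_home = t_bwd + mtb
    total = t_home + design.tail_s
    n = int(np.floor(total * fs)) + 1
    t = np.arange(n) / fs
    pos = np.tile(home, (n, 1))

    in_fwd = (t >= t_fwd) & (t < t_hold)
    tau_f = (t[in_fwd] - t_fwd) / mtf
    pos[in_fwd] = home + np.outer(minimum_jerk_profile(tau_f), target - home)
    pos[in_fwd, 0] = forward_x(tau_f)

    in_hold = (t >= t_hold) & (t < t_bwd)
    pos[in_hold] = endpoint

    in_bwd = (t >= t_bwd) & (t < t_home)
    tau_b = (t[in_bwd] - t_bwd) / mtb
    pos[in_bwd] = endpoint + np.outer(minimum_jerk_profile(tau_b), home - endpoint)

    events = {
        "stimulus": t_stim,
        "home_release": t_fwd,
        "home_return": t_home,
        "addressee_release": t_home + 0.25,
        "addressee_select": t_home + 0.25 + mta_ms / 1e3,
    }

    # --- ground truth (before noise)
    truth_bounds = PhaseBounds(
        t_stimulus=t_stim,
        t_release=t_fwd,
        forward_onset=t_fwd + f_up,
        forward_offset=t_fwd + f_down,
        hold_onset=t_fwd + f_down,
        hold_offset=t_bwd + b_up,
        backward_onset=t_bwd + b_up,
        backward_offset=t_bwd + b_down,
    )

    tau_dense = np.linspace(0.0, 1.0, 2001)
    dense = home + np.outer(minimum_jerk_profile(tau_dense), target - home)
    dense[:, 0] = forward_x(tau_dense)
    seglen = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    tl_cm = float(seglen.sum() * 1e2)
    vel_dense = np.gradient(dense, tau_dense * mtf, axis=0)
    speed_dense = np.linalg.norm(vel_dense, axis=1)
    k = int(np.argmax(speed_dense))
    ep = design.reporting_frame.to_mm(endpoint)
    truth = KinematicSummary(
        rtc_ms=rt_ms,
        mtf_ms=mtf_ms,
        ht_ms=ht_detected_ms,
        mtb_ms=mtb_ms,
        mta_ms=mta_ms,
        tl_cm=tl_cm,
        pv_cms=float(speed_dense[k] * 1e2),
        rtpv_pct=float(100.0 * tau_dense[k]),
        epx_mm=float(ep[0]),
        epy_mm=float(ep[1]),
        epz_mm=float(ep[2]),
    )

    # --- sensor noise and quantization
    if noise.position_noise_sd_mm > 0:
        pos = pos + rng.normal(0.0, noise.position_noise_sd_mm * 1e-3, size=pos.shape)
    if noise.resolution_mm > 0:
        step = noise.resolution_mm * 1e-3
        pos = np.round(pos / step) * step

    # --- correctness flags
    u = rng.random()
    comm_ok, addr_ok = True, True
    if u < effects.p_both_error:
        comm_ok = addr_ok = False
    elif u < effects.p_both_error + effects.p_communicator_error:
        comm_ok = False
    elif u < effects.p_both_error + effects.p_communicator_error + effects.p_addressee_error:
        addr_ok = False

    series = TrajectorySeries(time=t, position=pos, sampling_rate=fs, events=events)
    return SimulatedTrial(
        trial_id="trial",
        subject=0,
        block=0,
        trial_in_block=0,
        action=action,
        addressee=addressee,
        sign=sign,
        series=series,
        truth_bounds=truth_bounds,
        truth=truth,
        communicator_correct=comm_ok,
        addressee_correct=addr_ok,
    )


# ---------------------------------------------------------------------------
# Experiment-level synthesis
# ---------------------------------------------------------------------------

def _block_conditions(design: DesignSpec, subject: int) -> list[tuple[str, str]]:
    """(action, addressee) per block: addressee alternates every block, the
    action every two blocks; starting sides counterbalanced over subjects."""
    first_addr = ADDRESSEES[subject % 2]
    other_addr = ADDRESSEES[(subject + 1) % 2]
    first_act = ACTIONS[(subject // 2) % 2]
    other_act = ACTIONS[(subject // 2 + 1) % 2]
    out = []
    for b in range(design.n_blocks):
        addr = first_addr if b % 2 == 0 else other_addr
        act = first_act if (b // 2) % 2 == 0 else other_act
        out.append((act, addr))
    return out


def _sign_sequence(design: DesignSpec, blocks: list[tuple[str, str]], rng) -> list[str]:
    """Pseudo-random sign labels balanced within each (action, addressee)
    group of trials."""
    groups: dict[tuple[str, str], list[int]] = {}
    for b, cond in enumerate(blocks):
        idx = list(range(b * design.block_size, (b + 1) * design.block_size))
        groups.setdefault(cond, []).extend(idx)
    signs = [""] * design.n_trials_total
    for cond, idx in groups.items():
        n = len(idx)
        base = list(SIGNS) * (n // len(SIGNS))
        base += list(rng.choice(SIGNS, size=n - len(base), replace=False)) if n % len(SIGNS) else []
        order = rng.permutation(n)
        for k, i in enumerate(idx):
            signs[i] = base[order[k]]
    return signs


@dataclass
class Experiment:
    """All simulated trials plus the tidy trial table."""

    design: DesignSpec
    effects: EffectSpec
    noise: NoiseSpec
    seed: int
    trials: list[SimulatedTrial]

    @property
    def trial_table(self) -> pd.DataFrame:
        rows = []
        for tr in self.trials:
            ev = tr.series.events
            rows.append(
                {
                    "trial_id": tr.trial_id,
                    "subject": tr.subject,
                    "block": tr.block,
                    "trial_in_block": tr.trial_in_block,
                    "action": tr.action,
                    "addressee": tr.addressee,
                    "sign": tr.sign,
                    "t_stimulus_s": ev["stimulus"],
                    "t_home_release_s": ev["home_release"],
                    "t_home_return_s": ev["home_return"],
                    "t_addressee_release_s": ev["addressee_release"],
                    "t_addressee_select_s": ev["addressee_select"],
                    "communicator_correct": tr.communicator_correct,
                    "addressee_correct": tr.addressee_correct,
                }
            )
        return pd.DataFrame(rows)

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for tr in self.trials:
            rec = {"trial_id": tr.trial_id, "subject": tr.subject}
            rec.update({k: v for k, v in tr.truth.as_dict().items() if k != "reasons"})
            rows.append(rec)
        return pd.DataFrame(rows)

    def write(self, outdir) -> None:
        """Persist trajectories (one long-form file per subject), the trial
        table, and a JSON ground-truth sidecar."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        by_subject: dict[int, dict[str, TrajectorySeries]] = {}
        for tr in self.trials:
            by_subject.setdefault(tr.subject, {})[tr.trial_id] = tr.series
        for subj, trials in by_subject.items():
            write_trajectories(outdir / f"sub-{subj:02d}_trajectories.csv", trials)
        self.trial_table.to_csv(outdir / "trials.csv", index=False)
        truth = {
            "seed": self.seed,
            "trials": {
                tr.trial_id: {
                    "bounds": {
                        k: (None if isinstance(v, float) and np.isnan(v) else v)
                        for k, v in tr.truth_bounds.as_dict().items()
                    },
                    "summary": {
                        k: (None if isinstance(v, float) and np.isnan(v) else v)
                        for k, v in tr.truth.as_dict().items()
                        if k != "reasons"
                    },
                }
                for tr in self.trials
            },
        }
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(truth, fh)


def synthesize_experiment(
    design: DesignSpec = DesignSpec(),
    effects: EffectSpec = EffectSpec(),
    noise: NoiseSpec = NoiseSpec(),
    seed: int = 0,
) -> Experiment:
    """Generate a full multi-subject experiment.

    Subject random-effect offsets are drawn once per subject from
    independent normals with the between-subject sds in ``effects``; all
    randomness derives from ``seed`` through per-subject substreams, so
    generation is a pure function of (specs, seed).
    """
    trials: list[SimulatedTrial] = []
    for subj in range(design.n_subjects):
        rng = np.random.default_rng([int(seed), subj])
        sub = SubjectEffects(
            rt=rng.normal(0.0, effects.rt_subject_sd) if effects.rt_subject_sd else 0.0,
            mtf=rng.normal(0.0, effects.mtf_subject_sd) if effects.mtf_subject_sd else 0.0,
            # holds below the sub-threshold tail floor (~140 ms) are
            # kinematically impossible, so the subject offset is bounded below
            ht=float(np.clip(rng.normal(0.0, effects.ht_subject_sd), -55.0, None))
            if effects.ht_subject_sd
            else 0.0,
            mtb=rng.normal(0.0, effects.mtb_subject_sd) if effects.mtb_subject_sd else 0.0,
        )
        blocks = _block_conditions(design, subj)
        signs = _sign_sequence(design, blocks, rng)
        for i in range(design.n_trials_total):
            b, k = divmod(i, design.block_size)
            action, addressee = blocks[b]
            tr = synthesize_trial(
                (action, addressee, signs[i]),
                effects=effects,
                noise=noise,
                design=design,
                rng=rng,
                subject_effects=sub,
            )
            tr.trial_id = f"sub{subj:02d}_t{i:03d}"
            tr.subject = subj
            tr.block = b
            tr.trial_in_block = k
            trials.append(tr)
    return Experiment(design=design, effects=effects, noise=noise, seed=seed, trials=trials)
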