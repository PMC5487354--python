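"""Kinematic parameter and profile tests against geometric oracles."""

import numpy as np
import pandas as pd
import pytest

from pointkin import (
    EffectSpec,
    MissingCellError,
    NoiseSpec,
    ReportingFrame,
    TrajectorySeries,
    extract_parameters,
    lateral_contrast,
    lowpass_filter,
    segment_trial,
    synthesize_trial,
    time_normalize,
)
from pointkin.segmentation import PhaseBounds
from pointkin.trajectory import TooShortError

FS = 250.0
ORIGIN_FRAME = ReportingFrame(origin=(0.0, 0.0, 0.0))


def series_from_positions(pos, events=None):
    pos = np.asarray(pos, dtype=float)
    return TrajectorySeries(
        time=np.arange(len(pos)) / FS,
        position=pos,
        sampling_rate=FS,
        events=events or {"stimulus": 0.0},
    )


def bounds_covering(series, margin=2):
    t = series.time
    return PhaseBounds(
        t_stimulus=t[0],
        t_release=t[margin],
        forward_onset=t[margin],
        forward_offset=t[-margin - 1],
        hold_onset=t[-margin - 1],
        hold_offset=t[-1],
    )


class TestExtractParameters:
    def test_straight_reach_trajectory_length(self):
        n = 226
        pos = np.zeros((n, 3))
        pos[:, 1] = np.linspace(0, 0.3, n)
        s = series_from_positions(pos)
        summary = extract_parameters(s, bounds_covering(s, margin=0), ORIGIN_FRAME)
        assert summary.tl_cm == pytest.approx(30.0, abs=1e-9)

    def test_semicircular_detour_arclength(self):
        # oracle: dense numerical arc length of a semicircle of radius 0.15
        r = 0.15
        theta = np.linspace(0, np.pi, 300)
        pos = np.column_stack(
            [np.zeros_like(theta), r * (1 - np.cos(theta)) / 1.0, r * np.sin(theta)]
        )
        dense_theta = np.linspace(0, np.pi, 200_000)
        dense = np.column_stack(
            [np.zeros_like(dense_theta), r * (1 - np.cos(dense_theta)), r * np.sin(dense_theta)]
        )
        oracle_cm = np.sum(np.linalg.norm(np.diff(dense, axis=0), axis=1)) * 1e2
        assert oracle_cm == pytest.approx(np.pi * 15, rel=1e-6)
        s = series_from_positions(pos)
        summary = extract_parameters(s, bounds_covering(s, margin=0), ORIGIN_FRAME)
        assert summary.tl_cm == pytest.approx(oracle_cm, rel=0.01)

    def test_minimum_jerk_rtpv_near_half(self):
        tr = synthesize_trial(
            ("object", "left", "middle"),
            effects=EffectSpec.null(),
            noise=NoiseSpec.zero(),
            rng=0,
        )
        f = lowpass_filter(tr.series)
        b = segment_trial(f)
        summary = extract_parameters(f, b)
        # symmetric speed profile peaks at mid-movement; threshold trimming
        # keeps the relative position at 50% within a sample's resolution
        assert summary.rtpv_pct == pytest.approx(50.0, abs=1.0)
        assert summary.pv_cms == pytest.approx(tr.truth.pv_cms, rel=0.02)

    def test_invalid_bounds_propagate_flags(self):
        s = series_from_positions(np.zeros((100, 3)))
        bad = PhaseBounds(t_stimulus=0.0, reasons=("no movement detected",))
        summary = extract_parameters(s, bad)
        assert not summary.valid
        assert "no movement detected" in summary.reasons
        assert np.isnan(summary.tl_cm)

    def test_tl_rotation_invariant(self):
        rng = np.random.default_rng(0)
        pos = rng.normal(size=(50, 3)).cumsum(axis=0) * 0.01
        s = series_from_positions(pos)
        base = extract_parameters(s, bounds_covering(s, 0), ORIGIN_FRAME).tl_cm
        # a rigid rotation about z by 40 degrees
        a = np.deg2rad(40)
        R = np.array([[np.cos(a), -np.sin(a), 0], [np.sin(a), np.cos(a), 0], [0, 0, 1]])
        s2 = series_from_positions(pos @ R.T)
        rot = extract_parameters(s2, bounds_covering(s2, 0), ORIGIN_FRAME).tl_cm
        assert rot == pytest.approx(base, rel=1e-9)


class TestTimeNormalize:
    def test_linear_input_reproduced_exactly(self):
        n = 200
        pos = np.zeros((n, 3))
        pos[:, 1] = np.linspace(0.0, 0.4, n)
        s = series_from_positions(pos)
        b = bounds_covering(s)
        prof = time_normalize(s, b)
        assert prof.position.shape == (100, 3)
        expected = np.interp(
            np.linspace(b.forward_onset, b.forward_offset, 100), s.time, pos[:, 1]
        )
        np.testing.assert_allclose(prof.position[:, 1], expected, atol=1e-12)

    def test_endpoints_match_phase_bounds(self):
        tr = synthesize_trial(("mind", "right", "right"), rng=4, noise=NoiseSpec.zero())
        f = lowpass_filter(tr.series)
        b = segment_trial(f)
        prof = time_normalize(f, b)
        i0, i1 = f.index_at(b.forward_onset), f.index_at(b.forward_offset)
        # spline interpolates through the knots: ends within interpolation
        # tolerance of the nearest-sample positions
        assert np.linalg.norm(prof.position[0] - f.position[i0]) < 5e-4
        assert np.linalg.norm(prof.position[-1] - f.position[i1]) < 5e-4

    def test_pure_depth_movement_has_zero_lateral_derivative(self):
        n = 150
        pos = np.zeros((n, 3))
        pos[:, 1] = np.linspace(0, 0.3, n) ** 2
        s = series_from_positions(pos)
        prof = time_normalize(s, bounds_covering(s))
        np.testing.assert_allclose(prof.velocity[:, 0], 0.0, atol=1e-12)

    def test_too_few_samples(self):
        s = series_from_positions(np.zeros((3, 3)))
        with pytest.raises(TooShortError):
            time_normalize(s, bounds_covering(s, margin=0))


def _profile_labels(n_subj=3, per_cell=2):
    rows = []
    for subj in range(n_subj):
        for action in ("mind", "object"):
            for addressee in ("left", "right"):
                for sign in ("left", "middle", "right"):
                    for k in range(per_cell):
                        rows.append(
                            {
                                "subject": subj,
                                "action": action,
                                "addressee": addressee,
                                "sign": sign,
                            }
                        )
    return pd.DataFrame(rows)


class TestLateralContrast:
    def test_identical_conditions_zero_difference(self):
        labels = _profile_labels()
        pos = np.tile(np.linspace(0, 1, 100), (len(labels), 1))
        c = lateral_contrast(labels, pos)
        for by in ("sign", "addressee"):
            np.testing.assert_allclose(c.action_difference(by).to_numpy(), 0.0, atol=1e-12)

    def test_recovers_injected_early_shift_profile(self):
        # oracle: the injected bias field evaluated at the kinematic
        # normalized times the detected forward phase covers
        from dataclasses import replace as dc_replace

        from pointkin.simulate import _early_bump

        shift_mm = 5.0
        effects = dc_replace(EffectSpec.null(), early_lateral_shift_mm=shift_mm)
        labels, profs, tau_kin_by_sign = [], [], {}
        for subj in range(2):
            for action in ("mind", "object"):
                for addressee in ("left", "right"):
                    for sign in ("left", "middle", "right"):
                        tr = synthesize_trial(
                            (action, addressee, sign),
                            effects=effects,
                            noise=NoiseSpec.zero(),
                            rng=0,
                        )
                        f = lowpass_filter(tr.series)
                        b = segment_trial(f)
                        prof = time_normalize(f, b)
                        labels.append(
                            {"subject": subj, "action": action,
                             "addressee": addressee, "sign": sign}
                        )
                        profs.append(prof.position[:, 0])
                        # map the measured grid back to kinematic tau
                        t0 = tr.series.events["home_release"]
                        mtf = tr.truth.mtf_ms / 1e3
                        grid = np.linspace(b.forward_onset, b.forward_offset, 100)
                        tau_kin_by_sign[sign] = (grid - t0) / mtf
        c = lateral_contrast(pd.DataFrame(labels), np.array(profs))
        diff = c.action_difference(by="sign") * 1e3  # mm
        for sign, direction in (("left", -1.0), ("right", 1.0)):
            tau_kin = tau_kin_by_sign[sign]
            expected = direction * shift_mm * _early_bump(tau_kin)
            observed = diff.loc[sign].to_numpy()
            assert np.max(np.abs(observed[tau_kin < 0.1])) < 0.2
            np.testing.assert_allclose(observed, expected, atol=0.35)

    def test_swapping_labels_negates_difference(self):
        rng = np.random.default_rng(5)
        labels = _profile_labels(n_subj=2, per_cell=1)
        pos = rng.normal(size=(len(labels), 100))
        c1 = lateral_contrast(labels, pos)
        swapped = labels.assign(
            action=labels["action"].map({"mind": "object", "object": "mind"})
        )
        c2 = lateral_contrast(swapped, pos)
        np.testing.assert_allclose(
            c1.action_difference("sign").to_numpy(),
            -c2.action_difference("sign").to_numpy(),
            atol=1e-12,
        )

    def test_missing_cell_is_named(self):
        labels = _profile_labels(n_subj=1, per_cell=1)
        keep = ~(
            (labels["action"] == "mind")
            & (labels["addressee"] == "left")
            & (labels["sign"] == "middle")
        )
        with pytest.raises(MissingCellError, match="middle"):
            lateral_contrast(labels[keep], np.zeros((keep.sum(), 100)))
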