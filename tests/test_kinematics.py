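"""Kinematic extraction: filtering, movement bounds, tPV%, valley counting."""

import numpy as np
import pytest
from scipy.optimize import brentq

from interceptsim.errors import (InvalidParameterError, NoMovementError,
                                 TooShortError)
from interceptsim.kinematics import (KinematicsConfig, Trajectory,
                                     count_corrections, detect_onset_offset,
                                     extract_profile, relative_tpv,
                                     smooth_and_differentiate)
from interceptsim.simulate import (composite_trajectory, minimum_jerk,
                                   minimum_jerk_acceleration,
                                   minimum_jerk_velocity)

FS = 200.0


def min_jerk_traj(d=27.7, mt=0.225, t0=0.2, tail=0.3, noise=0.0, rng=None):
    t = np.arange(0.0, t0 + mt + tail, 1 / FS)
    x = minimum_jerk(d, mt, t - t0)
    if noise > 0:
        x = x + rng.normal(0.0, noise, size=x.shape)
    return Trajectory(t, x, {"kind": "control"})


class TestSmoothing:
    def test_constant_trace(self):
        t = np.arange(0, 1, 1 / FS)
        _, v, a = smooth_and_differentiate(t, np.full_like(t, 3.7))
        assert np.allclose(v, 0.0, atol=1e-9)
        assert np.allclose(a, 0.0, atol=1e-6)

    def test_linear_trace(self):
        t = np.arange(0, 2, 1 / FS)
        k = 12.0
        _, v, a = smooth_and_differentiate(t, k * t)
        # trim the filter transient (0.3 s) at both ends
        sl = slice(60, -60)
        assert np.allclose(v[sl], k, rtol=1e-6)
        assert np.max(np.abs(a[sl])) < 1e-5

    def test_minimum_jerk_derivatives_match_analytic(self):
        # generous cutoff isolates differentiation accuracy from the
        # (separately tested) pass-band attenuation of the default filter
        traj = min_jerk_traj()
        _, v, a = smooth_and_differentiate(traj.t, traj.x, cutoff_hz=30.0)
        v_true = minimum_jerk_velocity(27.7, 0.225, traj.t - 0.2)
        a_true = minimum_jerk_acceleration(27.7, 0.225, traj.t - 0.2)
        # movement interior: the jerk steps at the movement boundaries are
        # a property of the signal, not of the differentiation
        interior = (traj.t > 0.2 + 0.02) & (traj.t < 0.2 + 0.225 - 0.02)
        rms_v = np.sqrt(np.mean((v - v_true)[interior] ** 2))
        rms_a = np.sqrt(np.mean((a - a_true)[interior] ** 2))
        assert rms_v < 0.01 * v_true.max()
        assert rms_a < 0.01 * a_true.max()

    def test_peak_velocity_amplitude_preserved(self):
        for mt in (0.200, 0.225, 0.250):
            traj = min_jerk_traj(mt=mt)
            _, v, _ = smooth_and_differentiate(traj.t, traj.x)
            pv_true = 1.875 * 27.7 / mt
            assert abs(v.max() - pv_true) / pv_true < 0.01

    def test_too_short_trace(self):
        with pytest.raises(TooShortError):
            smooth_and_differentiate(np.arange(5) / FS, np.zeros(5))


class TestOnsetOffset:
    def test_movement_time_matches_analytic_threshold_crossings(self):
        # 5% of PV crossed at analytic tau0 / 1-tau0 of a minimum jerk
        tau0 = brentq(lambda u: 30 * u**2 * (1 - u)**2 - 0.05 * 1.875,
                      1e-6, 0.5)
        fs = 1000.0
        for mt in (0.200, 0.250):
            t = np.arange(0.0, mt + 0.4, 1 / fs)
            v = minimum_jerk_velocity(27.7, mt, t - 0.2)
            onset, offset = detect_onset_offset(v, fs)
            measured = (offset - onset) / fs
            expected = (1 - 2 * tau0) * mt
            assert abs(measured - expected) < 0.005

    def test_constant_velocity_onset_clamped_to_start(self):
        t = np.arange(0, 1, 1 / FS)
        v = np.full_like(t, 50.0)
        onset, offset = detect_onset_offset(v, FS)
        assert onset == 0
        assert offset == len(v) - 1

    def test_offset_after_second_peak_of_composite(self):
        traj = composite_trajectory(1, np.random.default_rng(0))
        _, v, a = smooth_and_differentiate(traj.t, traj.x)
        onset, offset = detect_onset_offset(v, FS)
        # the corrective pulse peaks after the main one; offset must lie
        # beyond the second velocity peak, not in the inter-peak dip
        from scipy.signal import find_peaks
        peaks, _ = find_peaks(v[onset:offset + 1], height=0.1 * v.max())
        assert len(peaks) >= 2
        assert offset > onset + peaks[-1]

    def test_no_movement_error(self):
        t = np.arange(0, 1, 1 / FS)
        with pytest.raises(NoMovementError):
            detect_onset_offset(np.full_like(t, 0.1), FS)


class TestRelativeTpv:
    def test_symmetric_profile_is_50(self):
        profile = extract_profile(min_jerk_traj())
        assert profile.tpv_pct == pytest.approx(50.0, abs=1.0)
        assert profile.n_cor == 0

    def test_late_correction_lowers_tpv(self):
        plain = extract_profile(min_jerk_traj())
        corrected = extract_profile(
            composite_trajectory(1, np.random.default_rng(3)))
        # corrective pulse extends the offset; PV stays on the main peak
        assert corrected.tpv_pct < plain.tpv_pct

    def test_pv_at_offset_is_100(self):
        assert relative_tpv(0, 10, 10, FS) == pytest.approx(100.0)

    def test_zero_mt_invalid(self):
        with pytest.raises(InvalidParameterError):
            relative_tpv(5, 5, 5, FS)


class TestCountCorrections:
    @staticmethod
    def _trace_with_interior_valley(depth):
        """peak 100, interior valley at 100-depth, second peak 100,
        deep terminal valley, rest — piecewise linear."""
        seg = np.concatenate([
            np.linspace(0, 100, 20),             # rise to first peak
            np.linspace(100, 100 - depth, 10),   # interior valley
            np.linspace(100 - depth, 100, 10),   # re-acceleration peak
            np.linspace(100, -100, 20),          # terminal deceleration
            np.linspace(-100, 0, 20),
        ])
        return seg

    def test_two_percent_rule_threshold_sides(self):
        below = self._trace_with_interior_valley(1.0)     # 1% of peak
        above = self._trace_with_interior_valley(2.5)     # 2.5% of peak
        _, n_below = count_corrections(below, 0, len(below) - 1)
        _, n_above = count_corrections(above, 0, len(above) - 1)
        assert n_below == 0
        assert n_above == 1

    def test_monophasic_scores_zero(self):
        profile = extract_profile(min_jerk_traj())
        assert profile.n_cor == 0

    def test_two_overlapping_submovements_score_one(self):
        # two overlapping minimum-jerk submovements, the second starting
        # 120 ms after the first, both comparable reaches
        t = np.arange(0, 0.8, 1 / FS)
        x = minimum_jerk(16.0, 0.2, t - 0.2) + minimum_jerk(10.0, 0.2, t - 0.32)
        profile = extract_profile(Trajectory(t, x, {}))
        assert profile.n_cor == 1

    def test_monotone_in_threshold(self):
        traj = composite_trajectory(2, np.random.default_rng(5),
                                    pos_noise_sd=0.05)
        _, v, a = smooth_and_differentiate(traj.t, traj.x)
        onset, offset = detect_onset_offset(v, FS)
        counts = [count_corrections(a, onset, offset, rel_depth=r)[1]
                  for r in (0.5, 0.2, 0.1, 0.05, 0.02, 0.01, 0.005)]
        assert counts == sorted(counts)   # n_cor never drops as rel_depth falls

    def test_invalid_threshold(self):
        with pytest.raises(InvalidParameterError):
            count_corrections(np.zeros(50), 0, 49, rel_depth=0.0)


class TestExtractProfile:
    def test_empty_trace_raises(self):
        with pytest.raises(TooShortError):
            extract_profile(Trajectory(np.arange(3) / FS, np.zeros(3), {}))

    def test_profile_invariants(self):
        profile = extract_profile(min_jerk_traj(noise=0.05,
                                                rng=np.random.default_rng(2)))
        assert profile.onset_idx < profile.offset_idx
        assert 0 < profile.tpv_pct <= 100
        assert profile.mt > 0
        assert profile.n_cor == sum(1 for v in profile.valleys
                                    if v.qualifies and not v.terminal)

    def test_crossing_reported_for_strike_line(self):
        profile = extract_profile(min_jerk_traj(), strike_x=27.7)
        # noise-free reach of 27.7 cm ends on the line at t0 + mt
        assert profile.t_cross == pytest.approx(0.2 + 0.225, abs=0.01)

    def test_unreachable_line_flagged(self):
        profile = extract_profile(min_jerk_traj(), strike_x=50.0)
        assert "no_crossing" in profile.flags
        assert profile.t_cross is None

    def test_config_validation(self):
        with pytest.raises(InvalidParameterError):
            KinematicsConfig(onset_frac=1.5)
        with pytest.raises(InvalidParameterError):
            KinematicsConfig(depth_mode="bogus")
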