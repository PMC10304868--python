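import logging

import numpy as np
import pytest

from gaitgrip.spm import CHANNELS
from gaitgrip.strides import (
    NEUTRAL_GC,
    DegenerateStrideError,
    EmptyEventsError,
    EventOrderError,
    InsufficientStridesError,
    NormalizedStride,
    RawTrial,
    StrideData,
    StrideEvents,
    average_trial,
    compute_gait_parameters,
    detect_heel_strikes,
    filter_strides,
    grid_columns,
    normalize_stride,
    process_cohort,
)
from gaitgrip.synthetic import (
    CohortSpec,
    default_templates,
    forward_velocity_profile,
    generate_cohort,
    synthesize_trial,
)


def _trial(seed=0, n_strides=11, noise=None, gs=1.3, dur=1.1):
    rng = np.random.default_rng(seed)
    samples, hs, to = synthesize_trial(rng, gs, dur, n_strides,
                                       noise_sd=noise)
    return RawTrial(samples=samples, side="left", subject_id="S", trial_id=0), hs, to


class TestRawTrialValidation:
    def test_too_short(self):
        with pytest.raises(ValueError, match="T >= 200"):
            RawTrial(np.zeros((100, 9)), "left", "S", 0)

    def test_non_finite(self):
        s = np.zeros((300, 9))
        s[5, 2] = np.nan
        with pytest.raises(ValueError, match="finite"):
            RawTrial(s, "left", "S", 0)

    def test_wrong_rate(self):
        with pytest.raises(ValueError, match="100"):
            RawTrial(np.zeros((300, 9)), "left", "S", 0, fs_hz=128)


class TestEventDetection:
    def test_known_heel_strikes_recovered(self):
        noise = {ch: sd for ch, sd in zip(
            CHANNELS, [0.25, 0.25, 0.25, 4.0, 4.0, 4.0, 0.5, 0.5, 0.5])}
        raw, hs_true, to_true = _trial(seed=3, n_strides=11, noise=noise)
        ev = detect_heel_strikes(raw)
        assert len(ev.hs) == 12
        assert np.abs(ev.hs - hs_true[:12]).max() <= 3
        assert np.abs(ev.to - to_true[:11]).max() <= 3

    def test_constant_zero_signal(self):
        raw = RawTrial(np.zeros((500, 9)), "left", "S", 0)
        with pytest.raises(EmptyEventsError):
            detect_heel_strikes(raw)

    def test_time_reversed_signal_rejected(self):
        raw, _, _ = _trial(seed=4)
        rev = RawTrial(raw.samples[::-1].copy(), "left", "S", 0)
        with pytest.raises(EventOrderError):
            detect_heel_strikes(rev)

    def test_events_invariants_enforced(self):
        with pytest.raises(EventOrderError):
            StrideEvents(hs=np.array([10, 100]), to=np.array([5]))
        with pytest.raises(EventOrderError):
            StrideEvents(hs=np.array([10, 100, 90]), to=np.array([50, 95]))


class TestNormalizeStride:
    def test_neutral_window_zero_mean(self):
        raw, hs, to = _trial(seed=1)
        ns = normalize_stride(raw.samples, hs[0], to[0], hs[1])
        neutral = ns.grid[:, NEUTRAL_GC[0] - 1:NEUTRAL_GC[1]]
        np.testing.assert_allclose(neutral.mean(axis=1), 0.0, atol=1e-10)
        assert ns.grid.shape == (9, 100)

    def test_identity_resampling_on_exact_grid(self):
        # stance of 60 samples, swing of 40: resampling is the identity
        rng = np.random.default_rng(2)
        samples = rng.normal(size=(220, 9))
        ns_cols = np.vstack([samples[50 + j] for j in range(100)]).T
        grid = normalize_stride(samples, 50, 110, 150).grid
        bias = ns_cols[:, NEUTRAL_GC[0] - 1:NEUTRAL_GC[1]].mean(axis=1)
        expected = ns_cols - bias[:, None]
        np.testing.assert_allclose(grid[6:], expected[6:], atol=1e-10)

    def test_vmax_constant_acceleration_closed_form(self):
        # forward acceleration a from the neutral window to stride end
        a = 2.0
        samples = np.zeros((220, 9))
        hs, to, hs2 = 50, 110, 150
        n0 = hs + round(20 / 60 * (to - hs))
        samples[n0:, CHANNELS.index("Ay")] = -a  # forward = -A_y
        samples[:, CHANNELS.index("Az")] = 1.0   # avoid degenerate grid
        ns = normalize_stride(samples, hs, to, hs2)
        expected = a * (hs2 - n0) / 100.0
        assert ns.v_max == pytest.approx(expected, rel=0.02)

    def test_degenerate_stride(self):
        samples = np.zeros((300, 9))
        samples[:, 2] = 1.0
        with pytest.raises(DegenerateStrideError):
            normalize_stride(samples, 10, 70, 120)

    def test_velocity_normalization_skips_euler_channels(self):
        raw, hs, to = _trial(seed=6)
        ns = normalize_stride(raw.samples, hs[0], to[0], hs[1])
        raw_grid_ex = np.interp(
            hs[0] + np.arange(60) * (to[0] - hs[0]) / 60,
            np.arange(raw.samples.shape[0]), raw.samples[:, 6])
        # Euler channel is bias-removed but NOT divided by v_max
        assert np.std(ns.grid[6, :60]) == pytest.approx(
            np.std(raw_grid_ex), rel=1e-6)


def _stub_stride(duration, v_max):
    ns = NormalizedStride(grid=np.zeros((9, 100)), v_max=v_max)
    return StrideData(stride=ns, gps=np.zeros(20), duration_s=duration)


class TestFilterStrides:
    def test_thirteen_clean_keeps_seven(self):
        strides = [_stub_stride(1.0 + 0.001 * i, 5.0) for i in range(13)]
        assert len(filter_strides(strides)) == 7

    def test_gross_outlier_dropped(self):
        durations = [1.0, 1.01, 0.99, 1.0, 10.0, 1.02, 0.98, 1.0, 1.01, 0.99]
        strides = [_stub_stride(d, 5.0) for d in durations]
        kept = filter_strides(strides)
        assert len(kept) == 3
        assert all(s.duration_s < 5 for s in kept)

    def test_six_strides_error(self):
        with pytest.raises(InsufficientStridesError):
            filter_strides([_stub_stride(1.0, 5.0)] * 6)


class TestGaitParameters:
    def test_timing_parameters(self):
        raw, hs, to = _trial(seed=7, gs=1.3, dur=1.0)
        gp = compute_gait_parameters(raw.samples, hs[0], to[0], hs[1], 1.70)
        assert gp[10] == pytest.approx(0.6, abs=0.01)   # gp11 stance frac
        assert gp[11] == pytest.approx(0.4, abs=0.01)   # gp12 swing frac
        assert gp[10] + gp[11] == pytest.approx(1.0)
        assert gp[9] == pytest.approx(120.0)             # gp10 cadence

    def test_gait_velocity_and_vmax(self):
        raw, hs, to = _trial(seed=8, gs=1.4, dur=1.1)
        gp = compute_gait_parameters(raw.samples, hs[0], to[0], hs[1], 1.70)
        assert gp[1] == pytest.approx(1.4, rel=0.03)     # gp02
        assert gp[16] == pytest.approx(4 * 1.4, rel=0.03)  # gp17 peak
        assert gp[1] <= gp[16]

    def test_planted_dorsiflexion_angle(self):
        raw, hs, to = _trial(seed=9, dur=1.0)
        gp = compute_gait_parameters(raw.samples, hs[0], to[0], hs[1], 1.70)
        assert gp[2] == pytest.approx(31.6, abs=0.3)     # gp03, template max

    def test_missing_height(self):
        raw, hs, to = _trial(seed=10)
        with pytest.raises(ValueError, match="height"):
            compute_gait_parameters(raw.samples, hs[0], to[0], hs[1], None)


class TestAverageTrial:
    def test_identical_feet(self):
        raw, hs, to = _trial(seed=11)
        ns = normalize_stride(raw.samples, hs[0], to[0], hs[1])
        sd = StrideData(stride=ns, gps=np.arange(20.0), duration_s=1.1)
        avg = average_trial([sd], [sd])
        np.testing.assert_allclose(avg.grid, ns.grid)
        np.testing.assert_allclose(avg.gps, np.arange(20.0))

    def test_antisymmetric_feet_cancel(self):
        g = np.random.default_rng(1).normal(size=(9, 100))
        left = StrideData(NormalizedStride(grid=g, v_max=5.0),
                          gps=np.ones(20), duration_s=1.0)
        right = StrideData(NormalizedStride(grid=-g, v_max=5.0),
                           gps=-np.ones(20), duration_s=1.0)
        avg = average_trial([left], [right])
        np.testing.assert_allclose(avg.grid, 0.0, atol=1e-12)

    def test_single_foot_fallback_warns(self, caplog):
        g = np.zeros((9, 100))
        left = StrideData(NormalizedStride(grid=g, v_max=5.0),
                          gps=np.zeros(20), duration_s=1.0)
        with caplog.at_level(logging.WARNING):
            avg = average_trial([left], [])
        assert "single-foot" in caplog.text
        np.testing.assert_allclose(avg.grid, g)

    def test_both_empty(self):
        with pytest.raises(ValueError):
            average_trial([], [])


class TestEndToEnd:
    def test_row_accounting(self, male_frame_27):
        frame, prov = male_frame_27
        assert len(frame) == 27 * 4
        assert prov["n_rows"] == 108
        assert frame.groupby("subject_id").size().eq(4).all()

    def test_noise_free_template_recovery(self):
        spec = CohortSpec(n_subjects=3, seed=21, n_trials=1, noise_sd=0.0,
                          stride_duration=1.0, gs_dist=(1.3, 0.0))
        cohort, gt = generate_cohort(spec)
        frame, _ = process_cohort(cohort)
        grids = frame[grid_columns()].to_numpy().reshape(len(frame), 9, 100)

        phi = (np.arange(100)) / 100.0
        templates = default_templates()
        expected = np.empty((9, 100))
        dur = 1.0
        for c, ch in enumerate(CHANNELS):
            if ch == "Ay":
                v = forward_velocity_profile(phi, 1.3)
                tmpl = -np.gradient(v, phi * dur)
            else:
                tmpl = templates[ch](phi)
            expected[c] = tmpl
        expected -= expected[:, 20:25].mean(axis=1, keepdims=True)
        v_max = 4 * 1.3
        expected[:6] /= v_max

        for g in grids:
            num = np.sqrt(np.mean((g - expected) ** 2))
            den = np.sqrt(np.mean(expected ** 2))
            assert num / den < 0.01

    def test_gait_speed_recovery_noise_free(self):
        spec = CohortSpec(n_subjects=4, seed=22, n_trials=1, noise_sd=0.0)
        cohort, gt = generate_cohort(spec)
        frame, _ = process_cohort(cohort)
        truth = frame["subject_id"].map(gt.gait_speed).to_numpy()
        assert np.abs(frame["gp02"].to_numpy() / truth - 1).max() < 0.03
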