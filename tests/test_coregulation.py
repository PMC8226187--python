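"""Layer-2 analytics: PCA, wavelet coherence, circular stats, gaze, sway."""

import numpy as np
import pytest

from duetphase import coregulation as co
from duetphase.errors import (
    AlignmentError,
    BandError,
    CalibrationError,
    DegenerateMotionError,
    GeometryError,
)


class TestHeadPC1:
    def test_single_axis_motion_is_recovered(self):
        t = np.linspace(0, 10, 2000)
        pos = np.zeros((2000, 3))
        pos[:, 1] = 0.02 * np.sin(2 * np.pi * 1.2 * t)
        pc1, evr = co.head_pc1(pos)
        assert evr == pytest.approx(1.0)
        assert abs(np.corrcoef(pc1, pos[:, 1])[0, 1]) == pytest.approx(1.0)

    def test_output_is_zscored(self):
        rng = np.random.default_rng(0)
        pc1, _ = co.head_pc1(rng.normal(0, 1, (500, 3)))
        assert pc1.mean() == pytest.approx(0.0, abs=1e-12)
        assert pc1.std() == pytest.approx(1.0, abs=1e-12)

    def test_isotropic_noise_explains_about_one_third(self):
        rng = np.random.default_rng(1)
        _, evr = co.head_pc1(rng.normal(0, 1, (10_000, 3)))
        assert evr == pytest.approx(1 / 3, abs=0.05)

    def test_constant_motion_raises(self):
        with pytest.raises(DegenerateMotionError):
            co.head_pc1(np.ones((100, 3)))


class TestWaveletCoherence:
    def test_self_coherence_near_one_in_cone(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 2048)
        cm = co.wavelet_coherence(x, x, 20.0)
        assert cm.coherence.min() >= 0.0 and cm.coherence.max() <= 1.0
        assert cm.coherence[cm.in_cone].min() >= 0.99

    def test_pure_tone_pair_localizes_within_one_voice(self):
        fs, f0 = 20.0, 0.7
        t = np.arange(4096) / fs
        rng = np.random.default_rng(3)
        x = np.sin(2 * np.pi * f0 * t) + 0.2 * rng.normal(0, 1, len(t))
        y = np.sin(2 * np.pi * f0 * t + 0.3) + 0.2 * rng.normal(0, 1, len(t))
        cm = co.wavelet_coherence(x, y, fs)
        avg = np.nanmean(np.where(cm.in_cone, cm.coherence, np.nan), axis=1)
        peak = cm.freq_hz[np.nanargmax(avg)]
        assert max(peak / f0, f0 / peak) <= 2 ** (1 / 12)

    def test_independent_noise_has_low_median_coherence(self):
        medians = []
        for seed in range(20):
            rng = np.random.default_rng(700 + seed)
            cm = co.wavelet_coherence(
                rng.normal(0, 1, 1200), rng.normal(0, 1, 1200), 20.0
            )
            medians.append(np.median(cm.coherence[cm.in_cone]))
        assert np.median(medians) < 0.4

    def test_length_mismatch_raises(self):
        with pytest.raises(AlignmentError):
            co.wavelet_coherence(np.zeros(1200), np.zeros(1100), 20.0)

    def test_cwt_localization_agrees_with_pywavelets(self):
        """Cross-check the Morlet transform against an independent CWT."""
        import pywt

        fs, f0 = 20.0, 1.0
        t = np.arange(2048) / fs
        x = np.sin(2 * np.pi * f0 * t)
        freqs = 0.25 * 2.0 ** (np.arange(49) / 12)
        scales = 1.0 / (co._FOURIER_FACTOR * freqs)
        w = co._morlet_cwt(x, fs, scales)
        power = np.mean(np.abs(w[:, 200:-200]) ** 2, axis=1)
        mine = freqs[np.argmax(power)]
        # pywt's cmor(B, C): C = omega0/(2*pi) cycles/sample at scale 1
        fc = co.MORLET_OMEGA0 / (2 * np.pi)
        coefs, pywt_freqs = pywt.cwt(x, fc * fs / freqs, f"cmor2.0-{fc}",
                                     sampling_period=1 / fs)
        theirs = pywt_freqs[np.argmax(np.mean(np.abs(coefs[:, 200:-200]) ** 2, axis=1))]
        assert mine == pytest.approx(f0, rel=0.06)
        assert theirs == pytest.approx(f0, rel=0.06)
        assert mine == pytest.approx(theirs, rel=0.06)


class TestBandPhaseStats:
    def _map_with_angles(self, angles, coherence=None):
        n_f, n_t = 3, len(angles)
        phase = np.tile(angles, (n_f, 1))
        coh = np.ones((n_f, n_t)) if coherence is None else np.tile(coherence, (n_f, 1))
        return co.CoherenceMap(
            time_s=np.arange(n_t, dtype=float),
            freq_hz=np.array([1.0, 1.2, 1.4]),
            coherence=coh,
            phase_rad=phase,
            in_cone=np.ones((n_f, n_t), bool),
        )

    def test_equal_angles_give_that_mean_and_unit_resultant(self):
        stats = co.band_phase_stats(self._map_with_angles(np.full(100, np.radians(73.0))))
        assert stats.mean_angle_deg == pytest.approx(73.0, abs=1e-9)
        assert stats.resultant_length == pytest.approx(1.0, abs=1e-12)

    def test_uniform_angles_cancel(self):
        angles = 2 * np.pi * np.arange(2000) / 2000
        stats = co.band_phase_stats(self._map_with_angles(angles))
        assert stats.resultant_length < 0.05

    def test_rotation_invariance_of_resultant(self):
        rng = np.random.default_rng(5)
        angles = rng.vonmises(0.5, 2.0, 500)
        s0 = co.band_phase_stats(self._map_with_angles(angles))
        s1 = co.band_phase_stats(self._map_with_angles(angles + np.radians(40)))
        assert s1.resultant_length == pytest.approx(s0.resultant_length, abs=1e-9)
        assert s1.mean_angle_deg == pytest.approx(s0.mean_angle_deg + 40, abs=1e-6)

    def test_quarter_period_lag_gives_90_degrees(self):
        fs, f0 = 20.0, 1.2
        t = np.arange(4096) / fs
        x = np.sin(2 * np.pi * f0 * t)
        y = np.sin(2 * np.pi * f0 * (t - 1 / (4 * f0)))
        cm = co.wavelet_coherence(x, y, fs)
        stats = co.band_phase_stats(cm, (0.9, 1.5))
        assert stats.mean_angle_deg == pytest.approx(90.0, abs=3.0)
        assert stats.resultant_length > 0.9

    def test_empty_band_raises(self):
        with pytest.raises(BandError):
            co.band_phase_stats(self._map_with_angles(np.zeros(10)), band_hz=(5.0, 6.0))


class TestGazeAngle:
    def test_at_partner_zero_orthogonal_ninety(self):
        own = np.zeros((4, 3))
        partner = np.tile([1.0, 0, 0], (4, 1))
        at = np.tile([1.0, 0, 0], (4, 1))
        ortho = np.tile([0.0, 1, 0], (4, 1))
        assert np.allclose(co.gaze_angle(at, own, partner).angle_deg, 0.0)
        assert np.allclose(co.gaze_angle(ortho, own, partner).angle_deg, 90.0)

    def test_seating_geometry_at_60_degrees(self):
        ang = np.radians(60.0)
        own = np.zeros((10, 3))
        partner = np.tile([1.8 * np.cos(ang), 1.8 * np.sin(ang), 0.0], (10, 1))
        forward = np.tile([1.0, 0.0, 0.0], (10, 1))
        gz = co.gaze_angle(forward, own, partner)
        assert np.allclose(gz.angle_deg, 60.0, atol=1e-9)

    def test_rigid_rotation_invariance(self):
        rng = np.random.default_rng(6)
        own = rng.normal(0, 1, (50, 3))
        partner = own + rng.normal(0, 1, (50, 3))
        gaze = rng.normal(0, 1, (50, 3))
        gaze /= np.linalg.norm(gaze, axis=1, keepdims=True)
        theta = 0.7
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        a0 = co.gaze_angle(gaze, own, partner).angle_deg
        a1 = co.gaze_angle(gaze @ rot.T, own @ rot.T, partner @ rot.T).angle_deg
        assert np.allclose(a0, a1, atol=1e-9)

    def test_missing_gaze_propagates_nan(self):
        gaze = np.tile([1.0, 0, 0], (5, 1))
        gaze[2] = np.nan
        out = co.gaze_angle(gaze, np.zeros((5, 3)), np.tile([1.0, 0, 0], (5, 1)))
        assert np.isnan(out.angle_deg[2]) and np.isfinite(out.angle_deg[0])

    def test_coincident_heads_raise(self):
        with pytest.raises(GeometryError):
            co.gaze_angle(np.ones((3, 3)), np.zeros((3, 3)), np.zeros((3, 3)))


class TestSwayRecurrence:
    def _sway(self, n=1200, seed=7, step_at=None, step=3.0):
        rng = np.random.default_rng(seed)
        walk = np.cumsum(rng.normal(0, 0.05, (n, 4)), axis=0)
        base = 10.0 + walk - walk.mean(axis=0)
        if step_at is not None:
            base[step_at:] += step * np.array([1.0, -0.4, 0.6, -0.2])
        return base

    def test_calibrated_rr_hits_target(self):
        out = co.sway_recurrence(self._sway(), fs=10.0)
        assert out.achieved_rr == pytest.approx(0.10, abs=0.005)
        assert out.metrics.rr == pytest.approx(out.achieved_rr, abs=1e-9)

    def test_normalized_rp_properties(self):
        out = co.sway_recurrence(self._sway(), fs=10.0)
        rp = out.norm_rp
        assert rp.max() == pytest.approx(1.0)
        assert np.allclose(rp, rp.T, atol=1e-12)
        assert np.allclose(np.diag(rp), 0.0, atol=1e-12)

    def test_step_change_creates_block_structure(self):
        n = 1200
        out = co.sway_recurrence(self._sway(step_at=n // 2, step=4.0), fs=10.0)
        half = out.norm_rp.shape[0] // 2
        within = np.mean(out.norm_rp[:half, :half])
        across = np.mean(out.norm_rp[:half, half:])
        assert across > 2 * within

    def test_constant_sway_raises(self):
        with pytest.raises(CalibrationError):
            co.sway_recurrence(np.ones((500, 4)), fs=10.0)


class TestNodAnnotations:
    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "nods.csv"
        p.write_text("performer,time_s\n")
        events, overlay = co.read_nod_annotations(p)
        assert events == [] and overlay is None

    def test_bad_rows_report_line_numbers(self, tmp_path):
        p = tmp_path / "nods.csv"
        p.write_text("performer,time_s\n1,2.5\noops,not_a_number\n")
        with pytest.raises(ValueError) as exc:
            co.read_nod_annotations(p)
        assert "3" in str(exc.value)

    def test_nod_at_boundary_has_zero_offset(self, tmp_path):
        from duetphase.performance import Segment

        p = tmp_path / "nods.csv"
        p.write_text("performer,time_s\n1,10.0\n")
        segments = [Segment("stable", 0.0, 10.0), Segment("shifting", 10.0, 20.0)]
        events, overlay = co.read_nod_annotations(p, segments=segments)
        assert overlay.loc[0, "offset_s"] == pytest.approx(0.0)

    def test_simulator_nods_match_stable_bar_starts(
        self, noiseless_performance, tmp_path
    ):
        from duetphase import synthgen
        from duetphase.performance import Segment

        traces = synthgen.synthesize_motion(noiseless_performance, seed=2)
        files = synthgen.export_performance(noiseless_performance, traces, tmp_path)
        segments = [
            Segment(b.kind, b.start_s, b.end_s) for b in noiseless_performance.schedule
        ]
        events, overlay = co.read_nod_annotations(files["nods"], segments=segments)
        assert len(events) == 13
        assert np.abs(overlay["offset_s"].to_numpy()).max() <= 0.1
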