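"""Recurrence quantification against a brute-force line-census oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from duetphase.errors import AlignmentError, CalibrationError, InsufficientDataError
from duetphase.rqa import (
    RQAConfig,
    RecurrencePlot,
    calibrate_radius,
    delay_embed,
    joint_recurrence,
    recurrence_matrix,
    rqa_metrics,
    select_delay_ami,
    select_dim_fnn,
)


def oracle_metrics(mat, theiler, lmin, vmin):
    """O(n^2) reference implementation of RR / DET / TT by direct counting."""
    n = mat.shape[0]
    n_off = n_rec = 0
    for i in range(n):
        for j in range(n):
            if abs(i - j) > theiler:
                n_off += 1
                if mat[i, j]:
                    n_rec += 1
    if n_off == 0:
        return 0.0, 0.0, 0.0
    rr = n_rec / n_off
    if n_rec == 0:
        return rr, 0.0, 0.0
    # diagonal lines (both triangles, outside the Theiler band)
    on_long_diag = 0
    for k in list(range(theiler + 1, n)) + [-k for k in range(theiler + 1, n)]:
        diag = [mat[i, i + k] for i in range(n) if 0 <= i + k < n]
        run = 0
        for v in diag + [False]:
            if v:
                run += 1
            else:
                if run >= lmin:
                    on_long_diag += run
                run = 0
    det = on_long_diag / n_rec
    # vertical lines on the Theiler-masked matrix
    vlens = []
    for j in range(n):
        run = 0
        for i in range(n + 1):
            v = i < n and mat[i, j] and abs(i - j) > theiler
            if v:
                run += 1
            else:
                if run > 0:
                    vlens.append(run)
                run = 0
    long_v = [v for v in vlens if v >= vmin]
    tt = float(np.mean(long_v)) if long_v else 0.0
    return rr, det, tt


def _plot(mat, theiler=0, fs=1.0):
    return RecurrencePlot(np.asarray(mat, bool), fs, theiler, True)


def _cfg(lmin, vmin, fs=1.0):
    return RQAConfig(lmin_s=lmin / fs, vmin_s=vmin / fs)


class TestMetricsAgainstOracle:
    @given(
        n=st.integers(4, 20),
        theiler=st.integers(0, 2),
        lmin=st.integers(1, 3),
        density=st.floats(0.1, 0.9),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_random_matrices_match_oracle(self, n, theiler, lmin, density, seed):
        rng = np.random.default_rng(seed)
        mat = rng.random((n, n)) < density
        rr_o, det_o, tt_o = oracle_metrics(mat, theiler, lmin, lmin)
        m = rqa_metrics(_plot(mat, theiler), _cfg(lmin, lmin))
        assert m.rr == pytest.approx(rr_o, abs=1e-12)
        assert m.det == pytest.approx(det_o, abs=1e-12)
        assert m.tt == pytest.approx(tt_o, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_50x50_matrices_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mat = rng.random((50, 50)) < 0.15
        mat |= mat.T  # symmetric like a real recurrence plot
        rr_o, det_o, tt_o = oracle_metrics(mat, 1, 2, 2)
        m = rqa_metrics(_plot(mat, 1), _cfg(2, 2))
        assert (m.rr, m.det, m.tt) == pytest.approx((rr_o, det_o, tt_o), abs=1e-12)

    def test_sine_recurrence_plot_matches_oracle(self):
        t = np.linspace(0, 6 * np.pi, 300)
        cfg = RQAConfig(m=2, tau_s=5.0, radius=0.3, lmin_s=3.0, vmin_s=3.0, theiler_s=5.0)
        rp = recurrence_matrix(np.sin(t), cfg, fs=1.0)
        rr_o, det_o, tt_o = oracle_metrics(rp.matrix, rp.theiler, 3, 3)
        m = rqa_metrics(rp, cfg)
        assert (m.rr, m.det, m.tt) == pytest.approx((rr_o, det_o, tt_o), abs=1e-12)
        assert m.det > 0.9  # periodic signal: recurrences lie on diagonals

    def test_all_ones_matrix(self):
        m = rqa_metrics(_plot(np.ones((10, 10)), 1), _cfg(1, 1))
        assert m.rr == 1.0 and m.det == 1.0

    def test_isolated_recurrences_have_no_lines(self):
        # every-other-row-and-column lattice: all recurrent points isolated
        i, j = np.indices((12, 12))
        mat = (i % 2 == 0) & (j % 2 == 0)
        m = rqa_metrics(_plot(mat, 0), _cfg(2, 2))
        assert m.rr > 0
        assert m.det == 0.0 and m.tt == 0.0


class TestRecurrenceMatrix:
    def test_infinite_radius_gives_rr_one(self):
        rng = np.random.default_rng(0)
        cfg = RQAConfig(m=2, tau_s=1.0, radius=1e9)
        rp = recurrence_matrix(rng.normal(0, 1, 100), cfg, fs=1.0)
        m = rqa_metrics(rp, cfg)
        assert m.rr == 1.0

    def test_tiny_radius_gives_rr_zero(self):
        rng = np.random.default_rng(0)
        cfg = RQAConfig(m=2, tau_s=1.0, radius=1e-12)
        rp = recurrence_matrix(rng.normal(0, 1, 100), cfg, fs=1.0)
        assert rqa_metrics(rp, cfg).rr == 0.0

    def test_rr_monotone_in_radius(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 200)
        rrs = []
        for radius in np.linspace(0.05, 3.0, 12):
            cfg = RQAConfig(m=3, tau_s=2.0, radius=radius)
            rrs.append(rqa_metrics(recurrence_matrix(x, cfg, fs=1.0), cfg).rr)
        assert np.all(np.diff(rrs) >= 0)

    def test_periodic_series_has_periodic_diagonals(self):
        fs = 40.0
        t = np.arange(200) / fs
        cfg = RQAConfig(m=2, tau_s=0.25, radius=0.2, theiler_s=0.25)
        rp = recurrence_matrix(np.sin(2 * np.pi * t), cfg, fs=fs)
        # recurrences repeat at the 1 s period: row 0 hits near columns 40, 80...
        hits = np.flatnonzero(rp.matrix[0])
        hits = hits[hits > rp.theiler]
        assert np.any(np.abs(hits - 40) <= 2)

    def test_embedding_too_long_raises(self):
        with pytest.raises(InsufficientDataError):
            recurrence_matrix(np.arange(10.0), RQAConfig(m=5, tau_s=5.0), fs=1.0)


class TestJointRecurrence:
    def test_idempotent_and_identity(self):
        rng = np.random.default_rng(2)
        mat = rng.random((30, 30)) < 0.3
        r = _plot(mat, 1)
        assert np.array_equal(joint_recurrence(r, r).matrix, mat)
        ones = _plot(np.ones((30, 30)), 1)
        assert np.array_equal(joint_recurrence(r, ones).matrix, mat)

    def test_shape_mismatch_raises(self):
        with pytest.raises(AlignmentError):
            joint_recurrence(_plot(np.ones((5, 5))), _plot(np.ones((6, 6))))

    def test_independent_noise_follows_product_law(self):
        cfg = RQAConfig(m=2, tau_s=1.0, radius=0.5, theiler_s=2.0)
        diffs = []
        for seed in range(20):
            rng = np.random.default_rng(500 + seed)
            r1 = recurrence_matrix(rng.normal(0, 1, 300), cfg, fs=1.0)
            r2 = recurrence_matrix(rng.normal(0, 1, 300), cfg, fs=1.0)
            rr_j = rqa_metrics(joint_recurrence(r1, r2), cfg).rr
            rr_prod = rqa_metrics(r1, cfg).rr * rqa_metrics(r2, cfg).rr
            diffs.append(rr_j - rr_prod)
        diffs = np.array(diffs)
        se = diffs.std(ddof=1) / np.sqrt(len(diffs))
        assert abs(diffs.mean()) <= 3 * se + 1e-4


class TestWindowedMetrics:
    def test_windowed_values_match_oracle_on_submatrices(self):
        rng = np.random.default_rng(3)
        mat = rng.random((60, 60)) < 0.2
        rp = _plot(mat, 1, fs=1.0)
        cfg = _cfg(2, 2)
        m = rqa_metrics(rp, cfg, windowed=True, window_s=20, step_s=10)
        assert len(m.windowed) == 5
        t0, rr0, det0, tt0 = m.windowed[0]
        rr_o, det_o, tt_o = oracle_metrics(mat[:20, :20], 1, 2, 2)
        assert (rr0, det0, tt0) == pytest.approx((rr_o, det_o, tt_o), abs=1e-12)


class TestCalibrateRadius:
    def test_sway_series_calibrates_to_10_percent(self):
        rng = np.random.default_rng(1)
        walk = np.cumsum(rng.normal(0, 1, 120 * 40))
        b = 3.0
        sway = b - np.abs(np.mod(walk * 0.05 + b, 4 * b) - 2 * b)
        cfg = RQAConfig(m=5, tau_s=0.35)
        _, rr = calibrate_radius(sway, cfg, fs=40.0)
        assert 0.095 <= rr <= 0.105

    def test_half_target_on_noise_converges(self):
        rng = np.random.default_rng(2)
        cfg = RQAConfig(m=2, tau_s=1.0)
        _, rr = calibrate_radius(rng.normal(0, 1, 400), cfg, fs=1.0, target_rr=0.49)
        assert rr == pytest.approx(0.49, abs=0.005)

    def test_constant_series_raises(self):
        with pytest.raises(CalibrationError):
            calibrate_radius(np.ones(200), RQAConfig(m=2, tau_s=1.0), fs=1.0)


class TestEmbeddingSelection:
    def test_sine_delay_is_quarter_period(self):
        fs, period = 40.0, 2.0
        x = np.sin(2 * np.pi * np.arange(400) / fs / period)
        tau = select_delay_ami(x, fs)
        assert abs(tau - period / 4) <= 1.0 / fs

    def test_white_noise_falls_back_to_one_sample(self):
        rng = np.random.default_rng(0)
        assert select_delay_ami(rng.normal(0, 1, 500), 40.0) == pytest.approx(1 / 40.0)

    def test_constant_series_raises(self):
        with pytest.raises(InsufficientDataError):
            select_delay_ami(np.ones(300), 40.0)

    def test_sine_embeds_in_the_plane(self):
        fs = 50.0
        x = np.sin(2 * np.pi * np.arange(2000) / fs / 1.873)
        m, warn = select_dim_fnn(x, tau_s=1.873 / 4, fs=fs)
        assert m == 2 and not warn

    def test_iid_noise_sets_warning_flag(self):
        rng = np.random.default_rng(1)
        m, warn = select_dim_fnn(rng.normal(0, 1, 1000), tau_s=0.02, fs=50.0)
        assert warn

    def test_simulated_relative_phase_embeds_at_or_below_4(self, noiseless_segmentation):
        rel, _, _ = noiseless_segmentation
        x = np.cos(rel.dphi_wrapped[:4000])
        m, _ = select_dim_fnn(x, tau_s=0.3, fs=rel.fs)
        assert m <= 4


class TestDelayEmbed:
    def test_shapes(self):
        emb = delay_embed(np.arange(10.0), m=3, tau=2)
        assert emb.shape == (6, 3)
        assert np.array_equal(emb[0], [0, 2, 4])
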