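import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegecg.hrv import detect_rpeaks, lorenz_indices, segment_indices
from eegecg.recording import Recording, RRISeries
from eegecg.synth import gen_rri


def brute_force_sd(rri, ddof=1):
    """Oracle: build the 2-D Poincaré cloud, rotate 45°, take coordinate SDs."""
    pts = np.column_stack([rri.intervals[:-1], rri.intervals[1:]])
    theta = np.pi / 4
    rot = np.array([[np.cos(theta), np.sin(theta)], [-np.sin(theta), np.cos(theta)]])
    rotated = pts @ rot.T
    along = rotated[:, 0].std(ddof=ddof)  # identity-line direction
    perp = rotated[:, 1].std(ddof=ddof)
    return perp, along


class TestLorenzIndices:
    def test_matches_rotated_cloud_oracle(self):
        rri = gen_rri(300, 800.0, 25.0, 50.0, seed=42)
        ix = lorenz_indices(rri)
        sd1_o, sd2_o = brute_force_sd(rri)
        assert ix.sd1 == pytest.approx(sd1_o, rel=1e-12)
        assert ix.sd2 == pytest.approx(sd2_o, rel=1e-12)
        assert ix.csi == pytest.approx(sd2_o / sd1_o, rel=1e-12)
        assert ix.cvi == pytest.approx(np.log10(16 * sd1_o * sd2_o), rel=1e-12)

    def test_constant_series_degenerate(self):
        ix = lorenz_indices(RRISeries(np.full(50, 800.0)))
        assert ix.sd1 == 0 and ix.sd2 == 0
        assert not ix.defined
        assert np.isnan(ix.csi) and np.isnan(ix.cvi)

    def test_alternating_series_analytic_geometry(self):
        a, b = 780.0, 820.0
        x = np.tile([a, b], 100)
        ix = lorenz_indices(RRISeries(x), ddof=0)
        # all points on the anti-identity line: no along-identity spread
        assert ix.sd2 == pytest.approx(0.0, abs=1e-9)
        assert ix.sd1 == pytest.approx(abs(a - b) / np.sqrt(2), rel=1e-3)
        assert ix.csi == 0.0
        assert np.isnan(ix.cvi) and not ix.defined

    def test_generator_parameter_recovery(self):
        ix = lorenz_indices(gen_rri(400, 790.0, 20.0, 45.0, seed=5))
        assert ix.sd1 == pytest.approx(20.0, rel=0.15)
        assert ix.sd2 == pytest.approx(45.0, rel=0.15)
        assert ix.csi == pytest.approx(45.0 / 20.0, rel=0.15)

    def test_variance_partition(self):
        rri = gen_rri(5000, 800.0, 20.0, 45.0, seed=9)
        ix = lorenz_indices(rri)
        total = 2 * rri.intervals.var(ddof=1)
        assert ix.sd1**2 + ix.sd2**2 == pytest.approx(total, rel=0.02)

    @given(shift=st.floats(-200, 500), scale=st.floats(0.2, 5.0))
    @settings(max_examples=25, deadline=None)
    def test_csi_invariance_cvi_shift_under_rescaling(self, shift, scale):
        base = gen_rri(120, 800.0, 15.0, 35.0, seed=11)
        transformed = RRISeries(scale * (base.intervals + shift))
        ix0 = lorenz_indices(base)
        ix1 = lorenz_indices(transformed)
        assert ix1.csi == pytest.approx(ix0.csi, rel=1e-9)
        assert ix1.cvi == pytest.approx(ix0.cvi + 2 * np.log10(scale), abs=1e-9)

    def test_too_few_intervals_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            lorenz_indices(RRISeries(np.array([800.0, 810.0])))


class TestSegmentIndices:
    def test_exact_two_minute_series_partitions(self):
        rri = RRISeries(np.full(120, 1000.0))  # exactly 120 s
        seg = segment_indices(rri)
        # first and last minute together cover every beat exactly once
        assert seg.first_min.n_beats + seg.last_min.n_beats == seg.total.n_beats
        assert seg.rri_change == 0.0

    def test_change_scores_are_last_minus_first(self):
        rri = gen_rri(200, 800.0, 20.0, 45.0, seed=4)
        seg = segment_indices(rri)
        assert seg.csi_change == pytest.approx(seg.last_min.csi - seg.first_min.csi)
        assert seg.cvi_change == pytest.approx(seg.last_min.cvi - seg.first_min.cvi)
        assert seg.rri_change == pytest.approx(
            seg.last_min.mean_rri - seg.first_min.mean_rri
        )

    def test_stationary_series_changes_near_zero(self):
        changes = []
        for seed in range(30):
            rri = gen_rri(400, 800.0, 20.0, 45.0, seed=seed)
            seg = segment_indices(rri)
            changes.append([seg.csi_change, seg.rri_change])
        mean = np.mean(changes, axis=0)
        assert abs(mean[0]) < 0.15
        assert abs(mean[1]) < 5.0

    def test_shrinking_fast_spread_raises_csi(self):
        # CSI is a ratio: a fast spread (SD1) shrinking over the task raises it
        positive = 0
        for seed in range(100):
            rri = gen_rri(
                500, 800.0, 30.0, 45.0, sd1_trend_ms_per_min=-7.0, seed=seed
            )
            if segment_indices(rri).csi_change > 0:
                positive += 1
        assert positive >= 95

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="shorter than two"):
            segment_indices(RRISeries(np.full(60, 1000.0)))


class TestGenRri:
    def test_degenerate_constant(self):
        rri = gen_rri(100, 800.0, 0.0, 0.0, seed=0)
        np.testing.assert_array_equal(rri.intervals, 800.0)

    def test_seeded_determinism(self):
        a = gen_rri(200, 800.0, 20.0, 45.0, seed=3)
        b = gen_rri(200, 800.0, 20.0, 45.0, seed=3)
        np.testing.assert_array_equal(a.intervals, b.intervals)

    def test_nonpositive_intervals_rejected(self):
        with pytest.raises(ValueError):
            gen_rri(100, 5.0, 20.0, 45.0, seed=0)

    def test_mean_trend_applied(self):
        rri = gen_rri(400, 800.0, 10.0, 20.0, trend_ms_per_min=30.0, seed=1)
        seg = segment_indices(rri)
        # centres of first and last minute are ~4.4 min apart at 800 ms/beat
        assert seg.rri_change == pytest.approx(30.0 * (rri.duration_s / 60 - 1), rel=0.4)


class TestDetectRpeaks:
    @staticmethod
    def impulse_train(period_ms=800.0, fs=1000.0, n_beats=20, drop=None):
        offset = int(fs // 2)  # keep the first peak off the array boundary
        n = int(n_beats * period_ms / 1000.0 * fs) + offset + 1
        x = np.zeros(n)
        peaks = offset + (np.arange(n_beats) * period_ms / 1000.0 * fs).astype(int)
        if drop is not None:
            peaks = np.delete(peaks, drop)
        x[peaks] = 1.0
        return Recording(("ECG",), fs, x[None, :])

    def test_noise_free_train_exact_intervals(self):
        rri = detect_rpeaks(self.impulse_train())
        np.testing.assert_allclose(rri.intervals, 800.0)

    def test_missing_beat_doubles_one_interval(self):
        rri = detect_rpeaks(self.impulse_train(drop=10))
        assert rri.n_beats == 18  # 19 peaks -> 18 intervals
        assert np.sum(np.isclose(rri.intervals, 1600.0)) == 1

    def test_white_noise_rejected(self, rng):
        rec = Recording(("ECG",), 1000.0, rng.normal(size=(1, 20000)))
        with pytest.raises(ValueError):
            detect_rpeaks(rec)
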