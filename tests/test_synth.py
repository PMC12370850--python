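import numpy as np
import pytest

from eegecg.spectral import faa, psd, relative_band_power
from eegecg.synth import (
    SimConfig,
    expected_faa,
    expected_relative_band_power,
    gen_eeg,
    gen_paired_endpoints,
    gen_roi_series,
    gen_rri,
    gen_subject,
    iter_subjects,
    read_cohort,
    write_cohort,
)


class TestGenEeg:
    def test_seeded_determinism_bit_identical(self, amps):
        a = gen_eeg(["F3", "F4"], 250.0, 65.0, amps, faa_shift=0.1, seed=5)
        b = gen_eeg(["F3", "F4"], 250.0, 65.0, amps, faa_shift=0.1, seed=5)
        np.testing.assert_array_equal(a.data, b.data)

    def test_unknown_electrode_rejected(self, amps):
        with pytest.raises(ValueError, match="unknown electrode"):
            gen_eeg(["F3", "XX"], 250.0, 65.0, amps, seed=0)

    def test_too_short_recording_rejected(self, amps):
        with pytest.raises(ValueError, match="too short"):
            gen_eeg(["F3", "F4"], 250.0, 50.0, amps, seed=0)

    def test_symmetric_amplitudes_give_null_faa(self, small_eeg):
        # faa_shift = 0: FAA is zero up to Monte-Carlo noise
        assert abs(faa(small_eeg).value) < 0.03

    def test_band_power_matches_parseval_prediction(self, small_eeg, amps):
        # the oracle neglects filter-skirt leakage, so it is asserted on the
        # bands that dominate their neighbours, where leakage is relatively small
        spec = psd(small_eeg)
        for band, lohi in (
            ("delta", (1.0, 4.0)),
            ("alpha", (8.0, 13.0)),
            ("gamma", (30.0, 60.0)),
        ):
            measured = relative_band_power(spec, lohi)[0]
            predicted = expected_relative_band_power(amps, 5.0, band, small_eeg.fs)
            assert measured == pytest.approx(predicted, rel=0.10)

    def test_injected_asymmetry_matches_parseval_prediction(self, amps):
        rec = gen_eeg(
            ["F3", "F4"], 250.0, 180.0, amps, faa_shift=0.2, noise_sd=5.0, seed=21
        )
        predicted = expected_faa(amps, 5.0, 0.2, 250.0)
        assert faa(rec).value == pytest.approx(predicted, rel=0.10)

    def test_per_channel_amplitude_map(self):
        amps = {
            "F3": {"alpha": 20.0},
            "F4": {"alpha": 5.0},
        }
        rec = gen_eeg(["F3", "F4"], 250.0, 65.0, amps, noise_sd=1.0, seed=2)
        assert rec.channel("F3").std() > 2 * rec.channel("F4").std()


class TestGenRoiSeries:
    def test_unknown_roi_in_coupling_rejected(self):
        with pytest.raises(ValueError, match="unknown ROI"):
            gen_roi_series(["A1", "A2"], 250.0, 10.0, [("A1", "ZZ", "alpha", 5, 0.5)], seed=0)

    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            gen_roi_series(["A1", "A1"], 250.0, 10.0, seed=0)

    def test_lag_longer_than_series_rejected(self):
        with pytest.raises(ValueError, match="lag"):
            gen_roi_series(["A1", "A2"], 100.0, 2.0, [("A1", "A2", "alpha", 500, 0.5)], seed=0)

    def test_strength_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="strength"):
            gen_roi_series(["A1", "A2"], 100.0, 5.0, [("A1", "A2", "alpha", 5, 1.5)], seed=0)

    def test_coupling_preserves_variance(self):
        uncoupled = gen_roi_series(["A1", "A2"], 250.0, 60.0, (), seed=8)
        coupled = gen_roi_series(
            ["A1", "A2"], 250.0, 60.0, [("A1", "A2", "alpha", 10, 0.8)], seed=8
        )
        assert coupled.channel("A2").std() == pytest.approx(
            uncoupled.channel("A2").std(), rel=0.05
        )


class TestGenPairedCohort:
    @staticmethod
    def tiny_config(**kw):
        base = dict(
            n_subjects=2,
            seed=3,
            fs=128.0,
            duration_s=61.0,
            channels=("F3", "F4"),
            roi_labels=("A", "B"),
            coupling_spec=(),
        )
        base.update(kw)
        return SimConfig(**base)

    def test_subject_determinism(self):
        cfg = self.tiny_config()
        s1 = gen_subject(cfg, 0)
        s2 = gen_subject(cfg, 0)
        np.testing.assert_array_equal(s1.altruistic.eeg.data, s2.altruistic.eeg.data)
        np.testing.assert_array_equal(s1.selfish.rri.intervals, s2.selfish.rri.intervals)
        assert s1.order == s2.order

    def test_conditions_differ_and_subjects_differ(self):
        cfg = self.tiny_config()
        s0, s1 = list(iter_subjects(cfg))
        assert not np.array_equal(s0.altruistic.eeg.data, s0.selfish.eeg.data)
        assert not np.array_equal(s0.altruistic.eeg.data, s1.altruistic.eeg.data)

    def test_cohort_roundtrip_through_directory(self, tmp_path):
        cfg = self.tiny_config()
        write_cohort(tmp_path / "cohort", iter_subjects(cfg), config=cfg)
        back = read_cohort(tmp_path / "cohort")
        assert len(back) == 2
        assert back.truth.seed == cfg.seed
        fresh = gen_subject(cfg, 0)
        np.testing.assert_allclose(
            back.subjects[0].altruistic.eeg.data, fresh.altruistic.eeg.data, rtol=1e-7
        )
        np.testing.assert_allclose(
            back.subjects[0].selfish.rri.intervals, fresh.selfish.rri.intervals, rtol=1e-7
        )

    def test_config_validation(self):
        with pytest.raises(ValueError, match="n_subjects"):
            self.tiny_config(n_subjects=1)
        with pytest.raises(ValueError, match="fs"):
            self.tiny_config(fs=100.0)
        with pytest.raises(ValueError, match="duration"):
            self.tiny_config(duration_s=45.0)


class TestPairedEndpoints:
    def test_null_effect_centred(self):
        diffs = []
        for seed in range(200):
            x, y = gen_paired_endpoints(20, 0.0, seed=seed)
            diffs.append(np.mean(x - y))
        # mean of 200 cohort-mean differences ~ N(0, 1/sqrt(200*20))
        assert abs(np.mean(diffs)) < 0.05

    def test_effect_size_realised(self):
        ds = []
        for seed in range(300):
            x, y = gen_paired_endpoints(50, 0.5, seed=seed)
            d = (x - y).mean() / (x - y).std(ddof=1)
            ds.append(d)
        assert np.mean(ds) == pytest.approx(0.5, abs=0.05)
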