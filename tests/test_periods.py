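"""Unit tests for audio loading, period segmentation, and GCI perturbation."""

import numpy as np
import pytest

import vowelbayes as vb

from conftest import male_vowel_spec


@pytest.fixture()
def toy_segment(rng):
    return vb.SpeechSegment(samples=rng.standard_normal(800), fs=8000.0)


class TestLoadSegment:
    def test_same_rate_roundtrip_within_one_lsb(self, tmp_path, rng):
        x = rng.uniform(-0.8, 0.8, 500)
        x[np.argmax(np.abs(x))] = 1.0  # pin the peak so write_wav scale is 1
        path = tmp_path / "t.wav"
        vb.write_wav(path, x, 8000)
        seg = vb.load_segment(path, fs_target=8000)
        assert seg.fs == 8000
        assert np.max(np.abs(seg.samples - x)) <= 1.0 / 32768

    def test_downsample_length(self, tmp_path, rng):
        x = rng.standard_normal(1001)
        path = tmp_path / "t16.wav"
        vb.write_wav(path, x, 16000)
        seg = vb.load_segment(path, fs_target=8000)
        assert abs(len(seg.samples) - 1001 // 2) <= 1

    def test_time_window_selection(self, tmp_path, rng):
        x = rng.standard_normal(8000)
        path = tmp_path / "t.wav"
        vb.write_wav(path, x, 8000)
        seg = vb.load_segment(path, t_start=0.1, t_end=0.3)
        assert len(seg.samples) == 1600

    def test_empty_selection_raises(self, tmp_path, rng):
        path = tmp_path / "t.wav"
        vb.write_wav(path, rng.standard_normal(100), 8000)
        with pytest.raises(ValueError):
            vb.load_segment(path, t_start=0.5, t_end=0.2)


class TestSegmentPeriods:
    def test_partition_counts(self, toy_segment):
        gcis = vb.GCISequence(times=np.array([0.01, 0.02, 0.05, 0.08]))
        ps = vb.segment_periods(toy_segment, gcis)
        assert ps.n == 3
        idx = np.round(gcis.times * 8000).astype(int)
        assert ps.N == idx[-1] - idx[0]

    def test_partition_reproduces_samples(self, toy_segment):
        gcis = vb.GCISequence(times=np.array([0.01, 0.02, 0.05, 0.08]))
        ps = vb.segment_periods(toy_segment, gcis)
        idx = np.round(gcis.times * 8000).astype(int)
        recon = np.concatenate(ps.periods) * ps.norm_scale
        assert np.allclose(recon, toy_segment.samples[idx[0] : idx[-1]], atol=1e-15)

    def test_constant_signal_normalizes_to_one(self):
        seg = vb.SpeechSegment(samples=np.full(200, 0.5), fs=8000.0)
        ps = vb.segment_periods(seg, vb.GCISequence(times=np.array([0.0, 0.0125, 0.025])))
        assert ps.norm_scale == 0.5
        for p in ps.periods:
            assert np.all(p == 1.0)

    def test_normalization_idempotent(self, toy_segment):
        gcis = vb.GCISequence(times=np.array([0.0, 0.04, 0.08]))
        ps = vb.segment_periods(toy_segment, gcis)
        seg2 = vb.SpeechSegment(samples=np.concatenate(ps.periods), fs=8000.0)
        ps2 = vb.segment_periods(seg2, vb.GCISequence(times=np.array([0.0, 0.04, 0.08])))
        assert ps2.norm_scale == 1.0
        for a, b in zip(ps.periods, ps2.periods):
            assert np.array_equal(a, b)

    def test_max_abs_is_one(self, male_periods):
        assert max(np.max(np.abs(p)) for p in male_periods.periods) == 1.0

    def test_synthetic_vowel_period_lengths(self):
        """At F0=120 and fs 8 kHz the jittered periods are 66-67 samples."""
        for seed in range(5):
            vow = vb.synthesize_vowel(male_vowel_spec(seed=seed))
            seg = vb.SpeechSegment(samples=vow.waveform, fs=8000.0)
            ps = vb.segment_periods(seg, vb.GCISequence(times=vow.gci_times))
            assert set(ps.lengths.tolist()) <= {66, 67}

    def test_gci_outside_segment_raises(self, toy_segment):
        with pytest.raises(ValueError):
            vb.segment_periods(toy_segment, vb.GCISequence(times=np.array([0.01, 0.2])))

    def test_too_short_period_raises(self, toy_segment):
        with pytest.raises(ValueError):
            vb.segment_periods(
                toy_segment, vb.GCISequence(times=np.array([0.01, 0.0102]))
            )


class TestPerturbGCIs:
    GCIS = vb.GCISequence(times=np.array([0.0, 0.0083, 0.0168, 0.0251]))

    def test_zero_eps_is_identity(self):
        out = vb.perturb_gcis(self.GCIS, vb.PerturbationSpec(eps=0.0, n_draws=3))
        for g in out:
            assert np.allclose(g.times, self.GCIS.times, atol=1e-15)

    def test_shift_equals_period_error_exactly(self):
        """tau_i(eps) - tau_i = T_i - T_i(eps) to machine precision."""
        out = vb.perturb_gcis(self.GCIS, vb.PerturbationSpec(eps=0.1, n_draws=10, seed=2))
        T = self.GCIS.periods
        for g in out:
            shift = g.times[:-1] - self.GCIS.times[:-1]
            # recover the drawn T_i(eps) from the shift and verify the identity
            T_eps = T - shift
            assert np.all(T_eps > 0)
            assert np.allclose(shift, T - T_eps, rtol=0, atol=0)
            assert g.times[-1] == self.GCIS.times[-1]

    def test_perturbed_period_log_sd(self):
        """Empirical sd of log T_i(eps) over many draws matches eps."""
        eps = 0.1
        out = vb.perturb_gcis(
            self.GCIS, vb.PerturbationSpec(eps=eps, n_draws=1000, seed=7)
        )
        T = self.GCIS.periods
        draws = np.array([T - (g.times[:-1] - self.GCIS.times[:-1]) for g in out])
        assert np.std(np.log(draws)) == pytest.approx(eps, rel=0.10)

    def test_deterministic_given_seed(self):
        a = vb.perturb_gcis(self.GCIS, vb.PerturbationSpec(eps=0.2, n_draws=4, seed=5))
        b = vb.perturb_gcis(self.GCIS, vb.PerturbationSpec(eps=0.2, n_draws=4, seed=5))
        for g1, g2 in zip(a, b):
            assert np.array_equal(g1.times, g2.times)

    def test_invalid_eps_rejected(self):
        with pytest.raises(ValueError):
            vb.PerturbationSpec(eps=1.5)


def test_gci_file_roundtrip(tmp_path):
    g = vb.GCISequence(times=np.array([0.001, 0.0091, 0.0175]))
    path = tmp_path / "marks.gci"
    vb.write_gci_file(path, g)
    g2 = vb.read_gci_file(path)
    assert np.allclose(g.times, g2.times, atol=1e-9)
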