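import numpy as np
import pytest

from prfval.calibration import (
    OnOffScan,
    coherence,
    estimate_snr_from_scan,
    fit_cycle_sinusoid,
    modulation_amplitude_psc,
    pick_noise_quantile_voxels,
    psc,
    select_voxels,
    stimulus_frequency,
)


def make_onoff_voxel(amp_psc, noise_sd_psc, seed, mean=1000.0, n=128, tr=1.5,
                     n_cycles=8):
    """Raw-unit on/off voxel: sinusoidal modulation plus white noise."""
    rng = np.random.default_rng(seed)
    t = np.arange(n)
    sin = np.sin(2 * np.pi * n_cycles * t / n)
    return mean * (1 + amp_psc / 100 * sin + noise_sd_psc / 100 * rng.normal(size=n))


def flat_spectrum_voxel(amp_psc, noise_sd_psc, seed, mean=1000.0, n=128,
                        n_cycles=8):
    """On/off voxel whose noise has a constant-magnitude spectrum (random
    phases only), so spectral coherence is identical across voxels by
    construction — a deterministic fixture for the coherence filter."""
    rng = np.random.default_rng(seed)
    t = np.arange(n)
    sin = np.sin(2 * np.pi * n_cycles * t / n)
    phases = rng.uniform(0, 2 * np.pi, n // 2 + 1)
    spec = np.exp(1j * phases)
    spec[0] = 0.0
    noise = np.fft.irfft(spec, n)
    noise *= noise_sd_psc / noise.std()
    return mean * (1 + amp_psc / 100 * sin + noise / 100)


class TestStimulusFrequency:
    @pytest.mark.parametrize(
        "period,expected", [(24.0, 0.042), (1.0, 1.0), (10.0, 0.1)]
    )
    def test_frequency_values(self, period, expected):
        assert stimulus_frequency(period) == pytest.approx(expected, abs=5e-4)

    def test_non_positive_period_rejected(self):
        with pytest.raises(ValueError):
            stimulus_frequency(0.0)


class TestCoherence:
    def test_pure_sinusoid_far_exceeds_one(self):
        n, tr = 192, 1.5
        t = np.arange(n) * tr
        series = np.sin(2 * np.pi * t / 24.0)
        assert coherence(series, 1 / 24.0, tr) > 10

    def test_white_noise_coherence_near_one(self):
        # flat-spectrum oracle: stimulus bin is a typical bin
        vals = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            vals.append(coherence(rng.normal(size=192), 1 / 24.0, 1.5))
        assert 0.5 < np.median(vals) < 2.0

    def test_known_amplitude_ratio_recovered(self):
        # sinusoid amplitude ~10x the mean noise amplitude -> coherence ~10
        n, tr = 960, 1.5
        rng = np.random.default_rng(1)
        t = np.arange(n) * tr
        noise = rng.normal(size=n)
        noise_amp = np.abs(np.fft.rfft(noise)).mean()
        series = 10 * noise_amp / (n / 2) * np.sin(2 * np.pi * t / 24.0) + noise
        assert coherence(series, 1 / 24.0, tr) == pytest.approx(10, rel=0.4)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="window"):
            coherence(np.ones(10), 0.042, 1.5, window_bins=10)


class TestCycleSinusoidFit:
    def test_exact_recovery_of_model_class_input(self):
        n = 160
        t = np.arange(n)
        series = 3.0 * np.sin(2 * np.pi * 8 * t / n + 0.7) + 5.0
        amp, phase, fitted = fit_cycle_sinusoid(series, 8)
        assert amp == pytest.approx(3.0, abs=1e-9)
        assert np.sqrt(np.mean((series - fitted) ** 2)) < 1e-9

    def test_amplitude_recovery_under_white_noise(self):
        # least-squares oracle: 50-seed median within 5% at n=160
        amps = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n = 160
            t = np.arange(n)
            series = 2.0 * np.sin(2 * np.pi * 8 * t / n + 1.1) + rng.normal(0, 2, n)
            amps.append(fit_cycle_sinusoid(series, 8)[0])
        assert np.median(amps) == pytest.approx(2.0, rel=0.05)

    def test_constant_input_gives_zero_amplitude(self):
        amp, _, _ = fit_cycle_sinusoid(np.full(160, 7.0), 8)
        assert amp == pytest.approx(0.0, abs=1e-9)

    def test_invalid_cycle_count_rejected(self):
        with pytest.raises(ValueError):
            fit_cycle_sinusoid(np.ones(160), 0)


class TestVoxelSelection:
    def test_constructed_scan_keeps_exactly_three_voxels(self):
        """Six voxels built so each filter stage drops exactly one: a dim
        voxel fails the 75%-of-grand-mean filter, a spectrally noisy one
        fails the coherence filter, an over-strong modulation falls outside
        the 8-12% PSC band; three survive everything."""
        # quiet noise keeps the good voxels' peak-to-peak amplitude inside
        # the band (noise extremes add to the measured contrast)
        good = [flat_spectrum_voxel(10.0, 0.3, s) for s in range(3)]
        dim = flat_spectrum_voxel(10.0, 0.3, 3, mean=100.0)  # fails stage 1
        noisy = flat_spectrum_voxel(10.0, 3.0, 4)  # 10x noise floor: stage 2
        # coherence matched to the good voxels (amp and noise scaled alike)
        # but modulation above the band: dropped at stage 3
        strong = flat_spectrum_voxel(14.0, 0.42, 5)
        scan = OnOffScan(np.vstack(good + [dim, noisy, strong]), tr=1.5)
        survivors, counts = select_voxels(scan)
        assert sorted(survivors) == [0, 1, 2]
        assert counts == [5, 4, 3]

    def test_identical_voxels_all_survive(self):
        v = make_onoff_voxel(10.0, 0.3, 0)
        scan = OnOffScan(np.vstack([v] * 4), tr=1.5)
        survivors, counts = select_voxels(scan)
        assert len(survivors) == 4
        assert counts == [4, 4, 4]

    def test_all_zero_scan_empty_at_stage_one(self):
        scan = OnOffScan(np.zeros((5, 128)), tr=1.5)
        survivors, counts = select_voxels(scan)
        assert survivors.size == 0
        assert counts[0] == 0

    def test_stage_counts_never_increase(self):
        rng = np.random.default_rng(0)
        bold = np.vstack(
            [make_onoff_voxel(rng.uniform(2, 14), rng.uniform(0.5, 4), s)
             for s in range(12)]
        )
        _, counts = select_voxels(OnOffScan(bold, tr=1.5))
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_psc_modulation_amplitude_reads_half_peak_to_peak(self):
        v = make_onoff_voxel(10.0, 0.0, 0)
        assert modulation_amplitude_psc(v) == pytest.approx(10.0, rel=0.01)


class TestScanSNR:
    def test_recovers_analytic_snr(self):
        # analytic oracle: rms of A*sin is A/sqrt(2)
        amp, sd = 10.0, 3.0
        expected = 20 * np.log10((amp / np.sqrt(2)) / sd)
        snrs = []
        for seed in range(50):
            scan = OnOffScan(make_onoff_voxel(amp, sd, seed)[None, :], tr=1.5)
            snrs.append(estimate_snr_from_scan(scan, 0)[0])
        assert np.median(snrs) == pytest.approx(expected, abs=0.5)

    def test_noise_free_sinusoid_rejected_as_infinite(self):
        scan = OnOffScan(make_onoff_voxel(10.0, 0.0, 0)[None, :], tr=1.5)
        with pytest.raises(ValueError, match="infinite"):
            estimate_snr_from_scan(scan, 0)

    def test_pure_noise_voxel_strongly_negative(self):
        scan = OnOffScan(make_onoff_voxel(0.0, 5.0, 0)[None, :], tr=1.5)
        assert estimate_snr_from_scan(scan, 0)[0] < -10

    def test_quantile_picker_orders_by_noise(self):
        voxels = [make_onoff_voxel(10.0, sd, 1) for sd in (1.0, 2.0, 3.0, 4.0, 5.0)]
        scan = OnOffScan(np.vstack(voxels), tr=1.5)
        picks = pick_noise_quantile_voxels(scan, np.arange(5), quantiles=(1.0, 0.5, 0.0))
        assert list(picks) == [4, 2, 0]


class TestPSC:
    def test_zero_mean_by_construction(self):
        rng = np.random.default_rng(0)
        series = 500 + rng.normal(0, 5, 300)
        assert psc(series).mean() == pytest.approx(0.0, abs=1e-12)

    def test_zero_mean_series_rejected(self):
        with pytest.raises(ValueError):
            psc(np.array([1.0, -1.0]))
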