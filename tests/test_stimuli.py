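"""Stimulus synthesis: ITD mapping, levels, lab conditions, datasets."""

import numpy as np
import pytest
from scipy.signal import periodogram

from binauralnet import ec, stimuli


class TestWoodworth:
    def test_midline_is_zero(self):
        assert stimuli.woodworth_itd(0.0) == 0.0

    def test_antisymmetry(self):
        for az in (10.0, 45.0, 88.0):
            assert stimuli.woodworth_itd(-az) == pytest.approx(
                -stimuli.woodworth_itd(az)
            )

    def test_lateral_maximum_is_head_limit(self):
        assert stimuli.woodworth_itd(90.0) == pytest.approx(655.0, abs=1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            stimuli.woodworth_itd(91.0)

    def test_azimuth_grid_matches_sample_quantization(self):
        grid = stimuli.azimuth_grid()
        itds = stimuli.woodworth_itd(grid)
        # every grid azimuth maps exactly to a multiple of 50 us
        assert np.allclose(itds / 50.0, np.round(itds / 50.0), atol=1e-6)
        pos = grid[grid > 0]
        expected = [5.61, 11.27, 16.97, 22.76, 28.67, 34.73, 41.01,
                    47.56, 54.45, 61.80, 69.77, 78.60, 88.71]
        assert np.allclose(pos, expected, atol=0.05)
        steps = np.diff(pos)
        assert 5.5 < steps.min() < 5.8 and 9.9 < steps.max() < 10.4


class TestIpdToItd:
    def test_half_cycle_at_500(self):
        assert stimuli.ipd_to_itd(500.0, np.pi) == pytest.approx(1000.0)

    def test_zero_phase(self):
        assert stimuli.ipd_to_itd(500.0, 0.0) == 0.0

    def test_half_cycle_at_250(self):
        assert stimuli.ipd_to_itd(250.0, np.pi) == pytest.approx(2000.0)


class TestTone:
    def test_diotic_tone_identical_ears(self):
        pair = stimuli.make_tone(stimuli.StimulusSpec(tone_itd_us=0.0))
        assert np.array_equal(pair.left, pair.right)

    def test_one_sample_shift(self):
        spec = stimuli.StimulusSpec(tone_itd_us=50.0, tone_phase=0.3)
        pair = stimuli.make_tone(spec)
        # right ear is the source delayed by one sample
        assert np.allclose(pair.right[1:], pair.left[:-1], atol=1e-12)

    def test_rms_matches_level_convention(self):
        spec = stimuli.StimulusSpec(tone_level_db_spl=50.0)
        pair = stimuli.make_tone(spec)
        assert np.sqrt(np.mean(pair.left**2)) == pytest.approx(
            20e-6 * 10 ** (50 / 20), rel=1e-3
        )

    def test_ten_periods_in_400_samples(self):
        pair = stimuli.make_tone(stimuli.StimulusSpec(tone_phase=0.0))
        # exact periodicity with period 40 samples
        assert np.allclose(pair.left[:360], pair.left[40:], atol=1e-12)

    def test_unrepresentable_itd_rejected(self):
        with pytest.raises(ValueError):
            stimuli.make_tone(stimuli.StimulusSpec(tone_itd_us=5000.0))


class TestNoise:
    def test_deterministic_per_seed(self):
        spec = stimuli.StimulusSpec(seed=42, noise_itd_us=100.0)
        a, b = stimuli.make_noise(spec), stimuli.make_noise(spec)
        assert np.array_equal(a.left, b.left) and np.array_equal(a.right, b.right)

    def test_diotic_noise_identical_ears(self):
        pair = stimuli.make_noise(stimuli.StimulusSpec(seed=3))
        assert np.array_equal(pair.left, pair.right)

    def test_itd_is_integer_sample_shift_of_same_token(self):
        spec = stimuli.StimulusSpec(seed=5, noise_itd_us=200.0)
        pair = stimuli.make_noise(spec)
        ref = stimuli.make_noise(stimuli.StimulusSpec(seed=5, noise_itd_us=0.0))
        assert np.allclose(pair.left, ref.left)
        # right is the same token read 4 samples earlier
        assert np.allclose(pair.right[4:], pair.left[:-4])

    def test_overall_level(self):
        pair = stimuli.make_noise(stimuli.StimulusSpec(seed=11))
        level = 20 * np.log10(np.sqrt(np.mean(pair.left**2)) / 20e-6)
        assert level == pytest.approx(60.0, abs=0.5)

    def test_band_limited(self):
        from scipy.signal import sosfreqz

        # analytic expectation: white noise through the filter puts this
        # fraction of power outside the passband (the -3 dB skirts leak)
        w, h = sosfreqz(
            stimuli._bandpass_sos(stimuli.SAMPLE_RATE_HZ),
            worN=8192,
            fs=stimuli.SAMPLE_RATE_HZ,
        )
        p_analytic = np.abs(h) ** 2
        inband_a = (w >= 50) & (w <= 5000)
        frac_expected = p_analytic[~inband_a].sum() / p_analytic.sum()

        spec = stimuli.StimulusSpec(seed=7, n_samples_per_ear=40_000)
        pair = stimuli.make_noise(spec)
        f, p = periodogram(pair.left, fs=stimuli.SAMPLE_RATE_HZ)
        inband = (f >= 50) & (f <= 5000)
        frac_out = p[~inband].sum() / p.sum()
        assert frac_out < 0.1
        assert frac_out == pytest.approx(frac_expected, rel=0.5)

    def test_inverted_noise(self):
        spec = stimuli.StimulusSpec(seed=5, noise_inverted=True)
        pair = stimuli.make_noise(spec)
        assert np.allclose(pair.left, -pair.right)


class TestLabConditions:
    def test_noso_identical_ears(self):
        pair = stimuli.make_lab_stimulus("NoSo", seed=1)
        assert np.allclose(pair.left, pair.right)

    def test_nospi_noise_identical_tone_inverted(self):
        spec = stimuli.lab_condition_spec("NoSpi", seed=2)
        noise = stimuli.make_noise(spec)
        tone = stimuli.make_tone(spec)
        assert np.array_equal(noise.left, noise.right)
        # pi carrier shift = sign flip for a pure tone
        assert np.allclose(tone.right, -tone.left, atol=1e-9)

    def test_npiso_tone_identical_noise_negated(self):
        spec = stimuli.lab_condition_spec("NpiSo", seed=3)
        noise = stimuli.make_noise(spec)
        tone = stimuli.make_tone(spec)
        assert np.allclose(tone.left, tone.right)
        assert np.allclose(noise.right, -noise.left)

    def test_unknown_condition(self):
        with pytest.raises(ValueError):
            stimuli.make_lab_stimulus("NoSx")

    @pytest.mark.parametrize(
        "condition,expected_bmld",
        [("NoSo", 0.0), ("NoSpi", 10.73), ("NpiSpi", 0.0), ("NpiSo", 10.73)],
    )
    def test_ec_lags_reproduce_lab_bmlds(self, condition, expected_bmld):
        spec = stimuli.lab_condition_spec(condition, seed=0)
        assert ec.bmld_db(spec.ec_lags()) == pytest.approx(expected_bmld, abs=0.01)


class TestExamples:
    def test_colocated_target_equals_zero_bmld_rate(self):
        spec = stimuli.StimulusSpec(
            tone_level_db_spl=31.0, tone_itd_us=300.0, noise_itd_us=300.0, seed=1
        )
        ex = stimuli.make_example(spec)
        assert ex.target_rate == pytest.approx(69.0, abs=1e-6)

    def test_lateralized_tone_better_detected(self):
        co = stimuli.make_example(
            stimuli.StimulusSpec(tone_level_db_spl=30.0, seed=1)
        )
        lat = stimuli.make_example(
            stimuli.StimulusSpec(
                tone_level_db_spl=30.0, tone_itd_us=-655.0, seed=1
            )
        )
        assert lat.target_rate > co.target_rate

    def test_inaudible_tone_near_floor(self):
        ex = stimuli.make_example(
            stimuli.StimulusSpec(tone_level_db_spl=0.0, tone_itd_us=655.0, seed=2)
        )
        assert ex.target_rate < 53.0

    def test_mixture_power_additivity(self):
        # tone and noise are independent: powers should add on average
        rng = np.random.default_rng(0)
        excess = []
        for s in rng.integers(0, 2**31 - 1, size=40):
            spec = stimuli.StimulusSpec(tone_level_db_spl=55.0, seed=int(s))
            mix = stimuli.make_tone(spec) + stimuli.make_noise(spec)
            p_mix = np.mean(mix.left**2)
            p_expect = stimuli.spl_to_rms(55.0) ** 2 + stimuli.spl_to_rms(60.0) ** 2
            excess.append(p_mix / p_expect)
        assert np.mean(excess) == pytest.approx(1.0, abs=0.05)


class TestDatasets:
    def test_deterministic_per_seed(self):
        a = stimuli.make_dataset(64, seed=9)
        b = stimuli.make_dataset(64, seed=9)
        assert np.array_equal(a.inputs, b.inputs)
        assert np.array_equal(a.targets, b.targets)

    def test_split_sizes(self):
        ds = stimuli.make_dataset(100, seed=0)
        assert ds.train[0].shape[0] == 95 and ds.validation[0].shape[0] == 5

    def test_targets_in_valid_range(self):
        ds = stimuli.make_dataset(256, seed=1)
        # upper bound is open mathematically but saturates in floats
        assert np.all(ds.targets >= 50.0) and np.all(ds.targets <= 100.0)

    def test_azimuths_approximately_uniform(self):
        from scipy.stats import chisquare

        ds = stimuli.make_dataset(2000, seed=3)
        az = ds.manifest["tone_azimuth_deg"]
        counts, _ = np.histogram(az, bins=np.linspace(-90, 90, 10))
        assert chisquare(counts).pvalue > 0.01

    def test_vectorized_generation_matches_single_example_targets(self):
        ds = stimuli.make_dataset(32, seed=5)
        i = 7
        spec = stimuli.StimulusSpec(
            tone_level_db_spl=float(ds.manifest["tone_level_db_spl"][i]),
            tone_itd_us=float(ds.manifest["tone_itd_us"][i]),
            noise_itd_us=float(ds.manifest["noise_itd_us"][i]),
            seed=123,
        )
        assert stimuli.make_example(spec).target_rate == pytest.approx(
            float(ds.targets[i]), abs=1e-3
        )

    def test_dataset_tone_component_matches_manifest(self):
        ds = stimuli.make_dataset(16, seed=8)
        i = 3
        n = stimuli.N_SAMPLES_PER_EAR
        spec = stimuli.StimulusSpec(
            tone_level_db_spl=float(ds.manifest["tone_level_db_spl"][i]),
            tone_phase=float(ds.manifest["tone_phase_rad"][i]),
            tone_itd_us=float(ds.manifest["tone_itd_us"][i]),
        )
        tone = stimuli.make_tone(spec)
        # subtracting the analytic tone leaves the two noise channels,
        # which must be shifted copies of one token
        d = int(round(ds.manifest["noise_itd_us"][i] / 50.0))
        left_n = ds.inputs[i, :n] - tone.left
        right_n = ds.inputs[i, n:] - tone.right
        if d >= 0:
            a, b = left_n[: n - d], right_n[d:]
        else:
            a, b = left_n[-d:], right_n[: n + d]
        assert np.corrcoef(a, b)[0, 1] > 0.999

    def test_parametric_dataset(self):
        ds = stimuli.parametric_dataset(1000, seed=4)
        assert ds.inputs.shape == (1000, 4)
        assert np.all(ds.inputs >= 0) and np.all(ds.inputs <= 2000)
        # equal arrival-time differences -> zero BMLD
        eq = stimuli.parametric_dataset(10, seed=4).inputs[0]
        ts = (eq[1] - eq[0]) * 1e-6
        tn = (eq[3] - eq[2]) * 1e-6
        assert ds.targets[0] == pytest.approx(
            ec.bmld_db(ec.LagPair(ts, tn)), abs=1e-5
        )

    def test_roundtrip_npz(self, tmp_path):
        ds = stimuli.parametric_dataset(50, seed=2)
        path = tmp_path / "ds.npz"
        stimuli.save_dataset(ds, path)
        back = stimuli.load_dataset(path)
        assert np.array_equal(back.inputs, ds.inputs)
        assert back.n_train == ds.n_train
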