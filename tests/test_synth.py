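import numpy as np
import pandas as pd
import pytest

import prfval as pv
from prfval.hrf import sample_hrf
from prfval.prf import evaluate_gaussian
from prfval.synth import (
    SynthesisConfig,
    causal_convolve,
    convolve_and_scale,
    neural_response,
    noise_free_bold,
    response_contrast,
    synthesize_dataset,
    synthesize_voxel,
    voxel_seed,
)


class TestNeuralResponse:
    def test_zero_rf_gives_zero_series(self, sweep_stimulus):
        rf = np.zeros((101, 101))
        np.testing.assert_array_equal(neural_response(sweep_stimulus, rf), 0.0)

    def test_single_pixel_rf_projects_that_pixel_trace(self, sweep_stimulus):
        rf = np.zeros((101, 101))
        rf[50, 60] = 2.5
        resp = neural_response(sweep_stimulus, rf)
        np.testing.assert_allclose(
            resp, 2.5 * sweep_stimulus.aperture[50, 60, :].astype(float)
        )

    def test_linearity_in_gain(self, sweep_stimulus, grid):
        rf1 = evaluate_gaussian(pv.GaussianPRF(1.0, 2.0, 1.5, gain=1.0), grid)
        rf3 = evaluate_gaussian(pv.GaussianPRF(1.0, 2.0, 1.5, gain=3.0), grid)
        np.testing.assert_allclose(
            neural_response(sweep_stimulus, rf3),
            3.0 * neural_response(sweep_stimulus, rf1),
            rtol=1e-12,
        )

    def test_blank_frames_give_exactly_zero(self, sweep_stimulus, grid):
        rf = evaluate_gaussian(pv.GaussianPRF(0.0, 0.0, 3.0), grid)
        resp = neural_response(sweep_stimulus, rf)
        blank_mask = sweep_stimulus.aperture.sum(axis=(0, 1)) == 0
        assert blank_mask.any()
        np.testing.assert_array_equal(resp[blank_mask], 0.0)

    def test_shape_mismatch_rejected(self, sweep_stimulus):
        with pytest.raises(ValueError, match="shape"):
            neural_response(sweep_stimulus, np.zeros((50, 50)))

    def test_reversed_sweep_reverses_response(self, grid):
        fwd = pv.generate_aperture(
            pv.BarSweepSpec(sweep_directions_deg=(0.0,), blank_every=0), grid
        )
        bwd = pv.generate_aperture(
            pv.BarSweepSpec(sweep_directions_deg=(180.0,), blank_every=0), grid
        )
        rf = evaluate_gaussian(pv.GaussianPRF(3.0, 3.0, 2.0), grid)
        # the reversed aperture movie is bit-identical, so the responses
        # agree to summation-order rounding
        np.testing.assert_allclose(
            neural_response(fwd, rf), neural_response(bwd, rf)[::-1], atol=1e-10
        )
        assert np.array_equal(fwd.aperture, bwd.aperture[:, :, ::-1])


class TestConvolution:
    def test_delta_kernel_is_identity(self):
        x = np.sin(np.arange(50) * 0.3)
        np.testing.assert_allclose(causal_convolve(x, np.array([1.0])), x)

    def test_unit_sum_kernel_preserves_constant_after_ramp(self, canonical_hrf):
        k = sample_hrf(canonical_hrf)
        y = causal_convolve(np.ones(200), k)
        np.testing.assert_allclose(y[len(k) :], 1.0, atol=1e-12)

    def test_matches_direct_summation_oracle(self, canonical_hrf):
        # independent O(n*k) oracle
        rng = np.random.default_rng(3)
        x = rng.normal(size=120)
        k = sample_hrf(canonical_hrf)
        direct = np.array(
            [sum(k[j] * x[t - j] for j in range(len(k)) if 0 <= t - j) for t in range(120)]
        )
        np.testing.assert_allclose(causal_convolve(x, k), direct, atol=1e-10)

    def test_kernel_longer_than_series_rejected(self, canonical_hrf):
        with pytest.raises(ValueError, match="longer"):
            causal_convolve(np.ones(10), sample_hrf(canonical_hrf))

    def test_scaling_sets_peak_modulation(self, canonical_hrf):
        x = np.zeros(100)
        x[20:40] = 1.0
        out = convolve_and_scale(x, sample_hrf(canonical_hrf), amplitude_psc=10.0)
        assert np.max(np.abs(out)) == pytest.approx(10.0)

    def test_all_zero_response_stays_at_baseline(self, canonical_hrf):
        out = convolve_and_scale(
            np.zeros(100), sample_hrf(canonical_hrf), baseline=1.5
        )
        np.testing.assert_array_equal(out, 1.5)


class TestSynthesizeVoxel:
    def test_zero_noise_equals_noise_free_path(
        self, fig_truth, sweep_stimulus, canonical_hrf, noise_free_voxel
    ):
        k = sample_hrf(canonical_hrf)
        np.testing.assert_array_equal(
            noise_free_voxel, noise_free_bold(fig_truth, sweep_stimulus, k)
        )

    def test_determinism_with_seed(self, fig_truth, sweep_stimulus, canonical_hrf):
        a = synthesize_voxel(
            fig_truth, sweep_stimulus, canonical_hrf, pv.noise_preset("mid"), seed=9
        )
        b = synthesize_voxel(
            fig_truth, sweep_stimulus, canonical_hrf, pv.noise_preset("mid"), seed=9
        )
        np.testing.assert_array_equal(a, b)

    def test_end_to_end_gain_linearity(self, sweep_stimulus, canonical_hrf):
        silent = pv.noise_preset("none")
        b1 = synthesize_voxel(
            pv.GaussianPRF(3, 3, 2, gain=1.0), sweep_stimulus, canonical_hrf, silent
        )
        b3 = synthesize_voxel(
            pv.GaussianPRF(3, 3, 2, gain=3.0), sweep_stimulus, canonical_hrf, silent
        )
        np.testing.assert_allclose(b3, 3.0 * b1, rtol=1e-12)

    def test_one_response_excursion_per_sweep(self, fig_truth, sweep_stimulus, grid):
        # oracle: count threshold upcrossings of the pre-convolution neural
        # response; the default protocol has 8 sweeps, each crossing the pRF
        resp = neural_response(
            sweep_stimulus, evaluate_gaussian(fig_truth, grid)
        )
        above = resp > 0.25 * resp.max()
        upcrossings = int(np.sum(~above[:-1] & above[1:]) + above[0])
        assert upcrossings == 8

    def test_randomized_design_has_lower_response_contrast(
        self, fig_truth, sweep_stimulus, grid, canonical_hrf
    ):
        k = sample_hrf(canonical_hrf)
        rand = pv.generate_aperture(pv.BarSweepSpec(randomize=True, seed=2), grid)
        assert response_contrast(fig_truth, rand, k) < response_contrast(
            fig_truth, sweep_stimulus, k
        )


class TestSynthesizeDataset:
    def test_condition_grid_size(self, sweep_stimulus, canonical_hrf):
        config = SynthesisConfig(
            prfs=[pv.GaussianPRF(3, 3, 2)],
            hrfs={f"h{i}": spec for i, spec in enumerate(pv.default_hrf_set().values())},
            noise_levels=["none"],
            repetitions=5,
        )
        ds = synthesize_dataset(config, sweep_stimulus)
        assert ds.n_voxels == 1 * 4 * 1 * 5
        assert len(ds.truth) == ds.n_voxels

    def test_single_rep_equals_direct_voxel_synthesis(
        self, sweep_stimulus, canonical_hrf, fig_truth
    ):
        config = SynthesisConfig(
            prfs=[fig_truth], hrfs={"canonical": canonical_hrf},
            noise_levels=["none"], repetitions=1,
        )
        ds = synthesize_dataset(config, sweep_stimulus)
        expected = synthesize_voxel(
            fig_truth, sweep_stimulus, canonical_hrf, pv.noise_preset("none")
        )
        np.testing.assert_array_equal(ds.bold[0], expected)

    def test_master_seed_determinism(self, sweep_stimulus, canonical_hrf, fig_truth):
        config = SynthesisConfig(
            prfs=[fig_truth], hrfs={"canonical": canonical_hrf},
            noise_levels=["mid"], repetitions=3, master_seed=5,
        )
        a = synthesize_dataset(config, sweep_stimulus)
        b = synthesize_dataset(config, sweep_stimulus)
        np.testing.assert_array_equal(a.bold, b.bold)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_empty_condition_list_rejected(self, canonical_hrf):
        with pytest.raises(ValueError, match="non-empty"):
            SynthesisConfig(prfs=[], hrfs={"c": canonical_hrf})

    def test_voxel_seed_scheme_is_stable(self):
        assert voxel_seed(0, 0) == voxel_seed(0, 0)
        assert voxel_seed(0, 1) != voxel_seed(0, 0)
        assert 0 <= voxel_seed(123, 456) < 2**31


@pytest.fixture(scope="module")
def dataset(sweep_stimulus, canonical_hrf, fig_truth):
    config = SynthesisConfig(
        prfs=[fig_truth], hrfs={"canonical": canonical_hrf},
        noise_levels=["mid"], repetitions=3, master_seed=1,
    )
    return synthesize_dataset(config, sweep_stimulus)


class TestBidsIO:
    def test_round_trip_within_float_precision(self, dataset, tmp_path):
        pv.write_bids(dataset, tmp_path)
        back = pv.read_bids(tmp_path)
        assert np.max(np.abs(back.bold - dataset.bold)) < 1e-6
        assert back.tr == dataset.tr

    def test_layout_matches_bids_naming(self, dataset, tmp_path):
        pv.write_bids(dataset, tmp_path)
        assert list(tmp_path.glob("sub-*/func/*_bold.nii.gz"))
        assert list(tmp_path.glob("sub-*/func/*_bold.json"))

    def test_truth_table_row_per_voxel(self, dataset, tmp_path):
        pv.write_bids(dataset, tmp_path)
        tsv = next(tmp_path.glob("derivatives/prfsynth/sub-*/*_truth.tsv"))
        assert len(pd.read_csv(tsv, sep="\t")) == dataset.n_voxels

    def test_missing_layout_rejected_with_entity_name(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="sub"):
            pv.read_bids(tmp_path)
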