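"""Synthetic AIFs, ground-truth sampling, curve sets and phantoms."""

import numpy as np
import pytest

from renoperf import (
    AcquisitionSpec,
    AifShape,
    GroundTruthCenters,
    ParameterBounds,
    SevenCompParams,
    arterial_cnr,
    concentric_geometry,
    generate_experiment,
    make_aif,
    make_phantom,
    sample_ground_truth,
)
from renoperf.synthetic import (
    LABEL_CORTEX,
    LABEL_MEDULLA,
    LABEL_PARTIAL,
)


class TestMakeAif:
    def test_baseline_window_is_exactly_zero(self, spec):
        aif = make_aif(spec)
        assert np.all(aif.v[aif.t < spec.baseline_window] == 0.0)

    def test_nonnegative_everywhere(self, spec):
        for seed in range(5):
            assert np.all(make_aif(spec, rng_seed=seed).v >= 0)

    def test_auc_linear_in_amplitude(self, spec):
        a1 = make_aif(spec, AifShape(amplitude=1.0))
        a3 = make_aif(spec, AifShape(amplitude=3.0))
        assert a3.auc() == pytest.approx(3 * a1.auc(), rel=1e-12)

    def test_single_first_pass_peak_then_decreasing_tail(self, spec):
        aif = make_aif(spec)
        peak_idx = int(aif.v.argmax())
        assert aif.t[peak_idx] > spec.baseline_window
        # after the recirculation bump has passed, the tail decreases
        shape = AifShape()
        settle = spec.baseline_window + shape.recirc_delay + 3 * shape.recirc_peak_time
        tail = aif.v[aif.t > settle]
        assert np.all(np.diff(tail) <= 0)
        # the first-pass peak is the unique global maximum
        assert np.sum(aif.v == aif.v.max()) == 1

    def test_invalid_shape_rejected(self):
        with pytest.raises(ValueError):
            AifShape(first_pass_peak_time=-1.0)


class TestGroundTruthSampling:
    def test_tiny_spread_returns_centers(self):
        centers = GroundTruthCenters(rel_sd=1e-9)
        draw = sample_ground_truth(centers, 0)
        np.testing.assert_allclose(
            draw.to_array(), centers.centers.to_array(), rtol=1e-7
        )

    def test_same_seed_identical_draw(self):
        centers = GroundTruthCenters()
        a = sample_ground_truth(centers, 7)
        b = sample_ground_truth(centers, 7)
        assert a.to_dict() == b.to_dict()

    def test_draws_respect_bounds(self):
        centers = GroundTruthCenters()
        b = ParameterBounds.seven_comp_default()
        for seed in range(200):
            assert b.contains(sample_ground_truth(centers, seed).to_array())

    def test_monte_carlo_moments_match_stated_distribution(self):
        from scipy.stats import truncnorm

        centers = GroundTruthCenters()
        c = centers.centers.to_array()
        b = centers.bounds
        draws = np.array(
            [sample_ground_truth(centers, s).to_array() for s in range(10_000)]
        )
        mean = draws.mean(axis=0)
        sd = draws.std(axis=0, ddof=1)
        # redraw-until-in-bounds == truncated normal; oracle moments from scipy
        sigma = 0.2 * c
        a = (b.lower - c) / sigma
        bb = (b.upper - c) / sigma
        ref_mean = truncnorm.mean(a, bb, loc=c, scale=sigma)
        ref_sd = truncnorm.std(a, bb, loc=c, scale=sigma)
        assert np.all(np.abs(mean - ref_mean) <= 0.02 * np.abs(ref_mean) + 1e-12)
        assert np.all(np.abs(sd - ref_sd) <= 0.1 * ref_sd)

    def test_centers_outside_bounds_rejected(self):
        bad = SevenCompParams(1.5, 7.5, 60, 43, 77, 29, 41, 249, 0.4, 0.29)
        with pytest.raises(ValueError):
            GroundTruthCenters(
                centers=bad,
                bounds=ParameterBounds(
                    lower=np.array([0, 1, 50, 1, 1, 1, 1, 0, 0, 0], dtype=float),
                    upper=np.array([1.0, 20, 200, 100, 100, 100, 100, 1000, 1, 1]),
                ),
            )


class TestGenerateExperiment:
    def test_full_study_scale_yields_96_datasets(self):
        spec = AcquisitionSpec(dt=1.6, duration=60.0, baseline_window=20.0)
        datasets = generate_experiment(24, 4, seed=0, spec=spec)
        assert len(datasets) == 96

    def test_dataset_is_self_certifying(self):
        ds = generate_experiment(1, 1, seed=5)[0]
        re_cor, re_med = ds.regenerate_clean()
        np.testing.assert_array_equal(re_cor.v, ds.clean[0].v)
        np.testing.assert_array_equal(re_med.v, ds.clean[1].v)

    def test_unique_truths_and_noise(self):
        datasets = generate_experiment(2, 2, seed=1)
        truths = [tuple(ds.truth.to_array()) for ds in datasets]
        assert len(set(truths)) == len(datasets)
        noisy = [ds.noisy["c_cor"].v.tobytes() for ds in datasets]
        assert len(set(noisy)) == len(datasets)
        assert len({ds.seed for ds in datasets}) == len(datasets)

    def test_measured_cnr_near_target(self, spec):
        datasets = generate_experiment(6, 1, seed=2)
        cnrs = [arterial_cnr(ds.noisy["aif"], spec) for ds in datasets]
        assert abs(np.median(cnrs) - 150) <= 0.15 * 150


class TestPhantom:
    def test_noiseless_region_voxels_carry_region_curves(self, truth, aif):
        labels = concentric_geometry()
        ph = make_phantom(labels, truth, aif, sigma=0.0, seed=0)
        c_cor = ph.region_curves["cortex"].v
        cortex_voxels = ph.image4d[labels == LABEL_CORTEX]
        assert np.all(cortex_voxels == c_cor)
        c_med = ph.region_curves["inner_medulla"].v
        assert np.all(ph.image4d[labels == LABEL_MEDULLA] == c_med)

    def test_label_counts_follow_geometry(self, truth, aif):
        labels = concentric_geometry()
        ph = make_phantom(labels, truth, aif, sigma=0.01, seed=1)
        for code in (LABEL_CORTEX, LABEL_MEDULLA, LABEL_PARTIAL):
            assert (ph.labels == code).sum() == (labels == code).sum()
            assert (labels == code).sum() >= 50

    def test_partial_volume_voxels_are_bounded_mixtures(self, truth, aif):
        labels = concentric_geometry()
        ph = make_phantom(labels, truth, aif, sigma=0.0, seed=2)
        assert np.all((ph.alphas > 0.2) & (ph.alphas < 0.8))
        c_cor = ph.region_curves["cortex"].v
        c_med = ph.region_curves["inner_medulla"].v
        pv = ph.image4d[labels == LABEL_PARTIAL]
        lo = np.minimum(c_cor, c_med)[None, :]
        hi = np.maximum(c_cor, c_med)[None, :]
        assert np.all(pv >= lo - 1e-12) and np.all(pv <= hi + 1e-12)

    def test_cortex_mean_curve_within_noise_standard_error(self, truth, aif):
        labels = concentric_geometry()
        sigma = 0.02
        ph = make_phantom(labels, truth, aif, sigma=sigma, seed=3)
        mask = labels == LABEL_CORTEX
        mean_curve = ph.image4d[mask].mean(axis=0)
        se = sigma / np.sqrt(mask.sum())
        c_cor = ph.region_curves["cortex"].v
        assert np.all(np.abs(mean_curve - c_cor) < 5 * se)
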