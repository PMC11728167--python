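"""Synthetic kernel generator: silhouettes, masses, scenes, datasets, mixtures."""

import numpy as np
import pandas as pd
import pytest
from skimage import measure

from kernelbreak.features import extract_features
from kernelbreak.synth import (
    GenerationError,
    KernelSpec,
    SceneSpec,
    WeightModel,
    assign_weight,
    compose_scene,
    generate_dataset,
    generate_mixture,
    generate_silhouette,
    sample_kernel_spec,
)


class TestKernelSpec:
    def test_damage_class_consistency_enforced(self):
        with pytest.raises(ValueError):
            KernelSpec(class_label="unbroken", base_radius=20, damage_fraction=0.3)
        with pytest.raises(ValueError):
            KernelSpec(class_label="broken", base_radius=20, damage_fraction=0.0)

    def test_damage_fraction_bounded(self):
        with pytest.raises(ValueError):
            KernelSpec(class_label="broken", base_radius=20, damage_fraction=0.7)


class TestSilhouette:
    def test_default_spec_is_a_disc(self):
        mask = generate_silhouette(KernelSpec(class_label="unbroken", base_radius=20, seed=0))
        assert measure.label(mask, connectivity=1).max() == 1
        assert mask.sum() == pytest.approx(np.pi * 400, rel=0.02)

    def test_same_spec_same_seed_identical(self):
        spec = KernelSpec(
            class_label="broken", base_radius=30, elongation=1.4,
            boundary_roughness=0.05, damage_fraction=0.4, seed=99,
        )
        assert np.array_equal(generate_silhouette(spec), generate_silhouette(spec))

    @pytest.mark.parametrize("mode", ["half_plane", "wedge"])
    @pytest.mark.parametrize("damage", [0.2, 0.5])
    def test_damage_removes_stated_area_fraction(self, mode, damage):
        spec = KernelSpec(
            class_label="broken", base_radius=30, damage_fraction=damage,
            damage_mode=mode, seed=42,
        )
        mask = generate_silhouette(spec)
        intact = np.pi * 30**2
        assert mask.sum() == pytest.approx((1 - damage) * intact, rel=0.05)
        assert measure.label(mask, connectivity=1).max() == 1

    def test_elongation_stretches_long_axis(self):
        spec = KernelSpec(class_label="unbroken", base_radius=25, elongation=1.6, seed=1)
        fv = extract_features(generate_silhouette(spec))
        assert fv.R_a == pytest.approx(1.6, rel=0.08)


class TestWeightModel:
    def test_equal_area_equal_weight_without_noise(self):
        wm = WeightModel(sigma=0.0)
        spec = KernelSpec(class_label="unbroken", base_radius=20, seed=0)
        m = generate_silhouette(spec)
        assert assign_weight(m, spec, wm) == assign_weight(m.copy(), spec, wm)

    def test_power_law_quadrupled_area_times_eight(self):
        wm = WeightModel(sigma=0.0)
        s1 = KernelSpec(class_label="unbroken", base_radius=15, seed=0)
        s2 = KernelSpec(class_label="unbroken", base_radius=30, seed=0)
        m1, m2 = generate_silhouette(s1), generate_silhouette(s2)
        w1, w2 = assign_weight(m1, s1, wm), assign_weight(m2, s2, wm)
        assert w2 / w1 == pytest.approx(8.0, rel=0.03)

    def test_mean_unbroken_weight_near_target(self):
        # Monte-Carlo over the default population: lognormal area-allometry
        # model should average ~0.35 g per intact kernel
        rng = np.random.default_rng(2018)
        wm = WeightModel()
        weights = []
        for _ in range(1000):
            spec = sample_kernel_spec("unbroken", rng)
            mask = generate_silhouette(spec)
            weights.append(assign_weight(mask, spec, wm, rng))
        assert np.mean(weights) == pytest.approx(0.35, rel=0.15)

    def test_invalid_coefficients_rejected(self):
        with pytest.raises(ValueError):
            WeightModel(alpha=-1.0)
        with pytest.raises(ValueError):
            WeightModel(beta=0.0)


class TestComposeScene:
    def test_empty_scene_is_blank_noise(self):
        scene = SceneSpec(n_kernels=0, image_size=(100, 120), seed=3)
        image, masks, truth = compose_scene([], scene)
        assert masks == [] and len(truth) == 0
        assert image.shape == (100, 120)

    def test_zero_noise_gives_two_gray_levels(self):
        rng = np.random.default_rng(5)
        specs = [sample_kernel_spec("unbroken", rng) for _ in range(3)]
        scene = SceneSpec(n_kernels=3, image_size=(400, 400), noise_sd=0.0, seed=5)
        image, _, _ = compose_scene(specs, scene)
        assert set(np.unique(image)) == {40, 200}

    def test_truth_rows_match_masks_and_conserve_mass(self):
        rng = np.random.default_rng(8)
        specs = [sample_kernel_spec(c, rng) for c in ("broken", "unbroken", "broken")]
        scene = SceneSpec(n_kernels=3, image_size=(500, 500), seed=8)
        image, masks, truth = compose_scene(specs, scene)
        assert len(masks) == len(truth) == 3
        for mask, (_, row) in zip(masks, truth.iterrows()):
            assert mask.shape == (
                row.bbox_row1 - row.bbox_row0,
                row.bbox_col1 - row.bbox_col0,
            )
        assert (truth["true_weight_g"] > 0).all()

    def test_36_kernel_scene_has_36_disjoint_components(self):
        rng = np.random.default_rng(11)
        specs = [sample_kernel_spec("unbroken" if i % 2 else "broken", rng) for i in range(36)]
        scene = SceneSpec(n_kernels=36, noise_sd=0.0, seed=11)
        image, masks, truth = compose_scene(specs, scene)
        labels = measure.label(image > 120, connectivity=1)
        assert labels.max() == 36

    def test_unsegmentable_scene_spec_rejected(self):
        with pytest.raises(ValueError):
            SceneSpec(n_kernels=1, background_level=100, kernel_level=110, noise_sd=5)

    def test_placement_failure_names_kernel(self):
        rng = np.random.default_rng(2)
        specs = [sample_kernel_spec("unbroken", rng) for _ in range(4)]
        scene = SceneSpec(n_kernels=4, image_size=(150, 150), seed=2)
        with pytest.raises(GenerationError, match=r"kernel \d"):
            compose_scene(specs, scene)


class TestGenerateDataset:
    def test_default_split_counts(self, full_dataset):
        frame = full_dataset.frame
        counts = frame.groupby(["class", "split"]).size()
        assert counts[("broken", "calibration")] == 135
        assert counts[("broken", "prediction")] == 45
        assert counts[("unbroken", "calibration")] == 90
        assert counts[("unbroken", "prediction")] == 30

    def test_split_fraction_one_rejected(self):
        with pytest.raises(ValueError):
            generate_dataset(n_broken=8, n_unbroken=8, split_fraction=1.0)

    def test_same_seed_identical_split(self):
        d1 = generate_dataset(n_broken=10, n_unbroken=8, seed=77)
        d2 = generate_dataset(n_broken=10, n_unbroken=8, seed=77)
        pd.testing.assert_frame_equal(d1.frame, d2.frame)

    def test_class_feature_separation(self, full_dataset):
        # joint (e, R_r) histograms of the two classes overlap by < 20%,
        # so the defect-classification task is learnable by construction
        frame = full_dataset.frame.iloc[:300]
        hb, *_ = np.histogram2d(
            frame.loc[frame["class"] == "broken", "e"],
            frame.loc[frame["class"] == "broken", "R_r"],
            bins=12, range=[[0, 1], [0, 1]],
        )
        hu, *_ = np.histogram2d(
            frame.loc[frame["class"] == "unbroken", "e"],
            frame.loc[frame["class"] == "unbroken", "R_r"],
            bins=12, range=[[0, 1], [0, 1]],
        )
        overlap = np.minimum(hb / hb.sum(), hu / hu.sum()).sum()
        assert overlap < 0.20


class TestGenerateMixture:
    def test_target_rate_hit_within_half_point(self):
        _, _, _, truth = generate_mixture(15.0, rng=1)
        assert 14.5 <= truth.Z_s <= 15.5

    def test_zero_rate_all_unbroken(self):
        _, _, table, truth = generate_mixture(0.0, rng=2)
        assert (table["class"] == "unbroken").all()
        assert truth.Z_s == 0.0 and truth.m_s == 0.0

    def test_truth_satisfies_mass_ratio_identity(self):
        _, _, table, truth = generate_mixture(7.0, rng=3)
        assert truth.Z_s == truth.m_s / truth.M_i * 100
        # mass conservation: M_i is exactly the sum of per-kernel weights
        assert truth.M_i == pytest.approx(table["true_weight_g"].sum(), abs=1e-12)

    def test_out_of_range_target_rejected(self):
        with pytest.raises(ValueError):
            generate_mixture(120.0, rng=0)
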