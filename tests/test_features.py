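"""Descriptor bank: segmentation, colour/texture/shape descriptors, assembly."""

import numpy as np
import pytest

from conftest import NOISELESS_STAIN, noiseless_geometry
from leukoselect.errors import (
    BackboneUnavailableError,
    EmptyRegionError,
    SegmentationDegenerateError,
)
from leukoselect.features import (
    CellMask,
    ExtractorSpec,
    FeatureMatrix,
    color_features,
    extract_features,
    extract_sample,
    segment_cell,
    shape_features,
    standardize_matrix,
    texture_features,
)
from leukoselect.synthetic import (
    CellGeometry,
    ImageSample,
    StainParams,
    SyntheticDatasetSpec,
    render_cell,
    sample_dataset,
)


def _noiseless_sample(radius=30.0, nucleus_fraction=0.55, seed=0, size=96):
    return render_cell(
        noiseless_geometry(radius, nucleus_fraction),
        NOISELESS_STAIN,
        0,
        size,
        np.random.default_rng(seed),
    )


def _gray_image(value, size=48):
    return np.full((size, size, 3), value, dtype=float)


class TestSegmentation:
    def test_uniform_image_is_degenerate(self):
        with pytest.raises(SegmentationDegenerateError):
            segment_cell(_gray_image(1.0))

    def test_cell_mask_area_matches_known_disk(self):
        sample = _noiseless_sample(radius=30.0)
        mask = segment_cell(sample)
        expected = np.pi * 30.0**2
        assert abs(mask.mask.sum() - expected) / expected < 0.05

    def test_nucleus_is_subset_of_cell(self):
        for seed in range(5):
            sample = render_cell(
                CellGeometry(), StainParams(), 0, 96, np.random.default_rng(seed)
            )
            mask = segment_cell(sample)
            assert mask.nucleus_mask.sum() <= mask.mask.sum()
            assert not np.any(mask.nucleus_mask & ~mask.mask)


def _full_mask(size, nucleus=False):
    m = np.ones((size, size), dtype=bool)
    n = np.zeros_like(m)
    if nucleus:
        n[: size // 2] = True
    return CellMask(mask=m, nucleus_mask=n)


class TestColorFeatures:
    def test_constant_region_moments(self):
        img = _gray_image(0.5)
        f = color_features(img, _full_mask(48))
        for ch in "rgb":
            assert f[f"color_rgb_{ch}_mean"] == pytest.approx(0.5)
            assert f[f"color_rgb_{ch}_sd"] == 0.0
            assert f[f"color_rgb_{ch}_skew"] == 0.0  # degenerate-moment convention
            assert f[f"color_rgb_{ch}_kurt"] == 0.0

    def test_half_black_half_white_population_convention(self):
        img = np.zeros((48, 48, 3))
        img[24:] = 1.0
        f = color_features(img, _full_mask(48))
        for ch in "rgb":
            assert f[f"color_rgb_{ch}_mean"] == pytest.approx(0.5)
            assert f[f"color_rgb_{ch}_sd"] == pytest.approx(0.5)

    def test_empty_mask_rejected(self):
        empty = CellMask(mask=np.zeros((8, 8), bool), nucleus_mask=np.zeros((8, 8), bool))
        with pytest.raises(EmptyRegionError):
            color_features(_gray_image(0.5, 8), empty)

    def test_fixed_length_and_order(self):
        f = color_features(_gray_image(0.3), _full_mask(48, nucleus=True))
        assert len(f) == 30
        assert list(f.index[:2]) == ["color_rgb_r_mean", "color_rgb_r_sd"]
        assert f.index[-1] == "color_nucleus_hsv_v_mean"


class TestTextureFeatures:
    def test_constant_region_single_symbol_glcm(self):
        f = texture_features(_gray_image(0.5), _full_mask(48))
        assert f["texture_glcm_contrast"] == 0.0
        assert f["texture_glcm_energy"] == 1.0
        assert f["texture_glcm_homogeneity"] == 1.0
        assert f["texture_glcm_correlation"] == 0.0  # zero-variance convention

    def test_checkerboard_enumeration(self):
        # all horizontal neighbour pairs alternate, so off-diagonal mass is 1
        size = 8
        board = (np.indices((size, size)).sum(axis=0) % 2).astype(float)
        img = np.dstack([board] * 3)
        spec = ExtractorSpec(glcm_levels=2, glcm_offsets=((0, 1),))
        f = texture_features(img, _full_mask(size), spec)
        assert f["texture_glcm_contrast"] == pytest.approx(1.0)
        assert f["texture_glcm_energy"] == pytest.approx(0.5)

    def test_offsets_larger_than_region_are_dropped(self):
        from leukoselect.errors import TextureDegenerateError

        spec = ExtractorSpec(glcm_levels=2, glcm_offsets=((0, 100), (100, 0)))
        with pytest.raises(TextureDegenerateError):
            texture_features(_gray_image(0.5), _full_mask(48), spec)


class TestShapeFeatures:
    def test_square_circularity_approaches_pi_over_four(self):
        mask = np.zeros((96, 96), bool)
        mask[10:74, 10:74] = True  # side 64
        with pytest.warns(UserWarning, match="empty nucleus"):
            f = shape_features(CellMask(mask=mask, nucleus_mask=np.zeros_like(mask)))
        assert f["shape_cell_circularity"] == pytest.approx(np.pi / 4, abs=0.05)

    def test_disk_circularity_near_one(self):
        sample = _noiseless_sample(radius=30.0)
        f = shape_features(segment_cell(sample))
        assert 0.9 <= f["shape_cell_circularity"] <= 1.1

    def test_nucleus_ratio_in_unit_interval(self):
        for seed in range(5):
            sample = render_cell(CellGeometry(), StainParams(), 0, 96, np.random.default_rng(seed))
            f = shape_features(segment_cell(sample))
            assert 0.0 <= f["shape_nucleus_area_ratio"] <= 1.0

    def test_empty_nucleus_warns_and_zeroes(self):
        mask = np.zeros((48, 48), bool)
        mask[10:40, 10:40] = True
        with pytest.warns(UserWarning, match="empty nucleus"):
            f = shape_features(CellMask(mask=mask, nucleus_mask=np.zeros_like(mask)))
        assert f["shape_nucleus_area_ratio"] == 0.0
        assert f["shape_nucleus_circularity"] == 0.0


class TestAssembly:
    def test_default_families_give_forty_named_features(self, small_spec):
        fm = extract_features(sample_dataset(small_spec))
        assert fm.values.shape == (12, 40)
        assert len(fm.labels) == 12
        color = [n for n in fm.feature_names if n.startswith("color_")]
        texture = [n for n in fm.feature_names if n.startswith("texture_")]
        shape = [n for n in fm.feature_names if n.startswith("shape_")]
        assert (len(color), len(texture), len(shape)) == (30, 4, 6)
        # families concatenated in declared order
        assert fm.feature_names == color + texture + shape

    def test_pooled_standardization_identity(self, small_spec):
        fm = extract_features(sample_dataset(small_spec), ExtractorSpec(standardize="pooled"))
        sd = fm.values.std(axis=0)
        nonconstant = sd > 1e-9
        assert np.allclose(fm.values[:, nonconstant].mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(sd[nonconstant], 1.0, atol=1e-9)
        assert np.all(fm.values[:, ~nonconstant] == 0.0)

    def test_row_order_is_permutation_equivariant(self, small_spec):
        samples = sample_dataset(small_spec)
        fm = extract_features(samples)
        perm = np.random.default_rng(0).permutation(len(samples))
        fm_perm = extract_features([samples[i] for i in perm])
        assert np.array_equal(fm_perm.values, fm.values[perm])
        assert fm_perm.sample_ids == [fm.sample_ids[i] for i in perm]

    def test_quarter_turn_leaves_geometry_descriptors(self):
        sample = _noiseless_sample(radius=28.0, nucleus_fraction=0.6)
        rotated = ImageSample(np.rot90(sample.pixels).copy(), sample.label, "rot")
        f0 = shape_features(segment_cell(sample))
        f90 = shape_features(segment_cell(rotated))
        for name in ("shape_cell_area", "shape_cell_circularity", "shape_nucleus_area_ratio"):
            assert abs(f90[name] - f0[name]) <= 0.02 * abs(f0[name])

    def test_every_feature_finite_across_randomized_samples(self):
        # randomized geometry/stain sweep; each extraction must stay finite
        count = 0
        for seed in range(250):
            rng = np.random.default_rng(seed)
            geometry = CellGeometry(
                cell_radius_mean=rng.uniform(8, 14),
                cell_radius_sd=rng.uniform(0, 1.5),
                nucleus_fraction_mean=rng.uniform(0.2, 0.9),
                nucleus_fraction_sd=rng.uniform(0, 0.1),
                boundary_irregularity=rng.uniform(0, 0.25),
                texture_grain=rng.uniform(0, 0.2),
            )
            stain = StainParams(
                color_jitter_sd=rng.uniform(0, 0.1), pixel_noise_sd=rng.uniform(0, 0.1)
            )
            for rep in range(4):
                sample = render_cell(
                    geometry, stain, 0, 48, np.random.default_rng((seed, rep)), sample_id=f"s{seed}_{rep}"
                )
                row = extract_sample(sample, ExtractorSpec())
                assert np.all(np.isfinite(row.to_numpy()))
                count += 1
        assert count == 1000

    def test_csv_round_trip_is_lossless(self, small_spec, tmp_path):
        fm = extract_features(sample_dataset(small_spec))
        path = tmp_path / "features.csv"
        fm.to_csv(path)
        back = FeatureMatrix.from_csv(path)
        assert back.feature_names == fm.feature_names
        assert np.array_equal(back.values, fm.values)
        assert np.array_equal(back.labels, fm.labels)

    def test_train_only_standardization_uses_training_rows(self, small_spec):
        fm = extract_features(sample_dataset(small_spec))
        train = np.arange(8)
        fs = standardize_matrix(fm, train_indices=train)
        ref = fs.values[train]
        nonconstant = fm.values[train].std(axis=0) > 1e-12
        assert np.allclose(ref[:, nonconstant].mean(axis=0), 0.0, atol=1e-9)


class TestDeepEmbedAdapter:
    def test_backbone_unavailable_error_directs_to_descriptors(self, small_spec, tmp_path):
        from leukoselect.embeddings import deep_embed
        from leukoselect.synthetic import generate_dataset

        manifest = generate_dataset(small_spec, tmp_path)
        with pytest.raises(BackboneUnavailableError, match="descriptor bank"):
            deep_embed(manifest, "googlenet", tmp_path)

    def test_selectors_are_agnostic_to_feature_source(self):
        # rows shaped like a deep embedding are accepted by the selection layer unchanged
        from leukoselect.selection import FitnessSpec, pso_select, PsoParams

        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 10)
        emb = rng.normal(size=(20, 6))
        emb[y == 1, 0] += 3.0
        fm = FeatureMatrix(emb, [f"googlenet_emb_{i}" for i in range(6)], y, [str(i) for i in range(20)])
        result = pso_select(fm, FitnessSpec(rng_seed=0), PsoParams(iterations=10))
        assert result.mask.shape == (6,)
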