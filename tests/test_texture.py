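"""Texture features: closed-form cases, family cardinalities, grid properties."""

import numpy as np
import pytest

from acctex.synthetic import PhantomSpec, generate_phantom
from acctex.texture import (
    FAMILY_NAMES,
    FEATURE_NAMES,
    TextureExtractor,
    discretize,
    extract_all,
    extract_features,
    first_order_features,
    glcm_features,
    gldm_features,
    glrlm_features,
    glszm_features,
    glszm_matrix,
    ngtdm_features,
)
from acctex.voi import VitalVoiBuilder
from acctex.volumes import VOI, CasePhase, StudyCase, Volume


def _region(values, bin_width=25.0, mask=None):
    data = np.asarray(values, dtype=float)
    if data.ndim < 3:
        data = data.reshape((1,) * (3 - data.ndim) + data.shape)
    vol = Volume(data, phase="venous")
    voi = VOI(np.ones_like(data) if mask is None else mask, kind="tumour-gross")
    return vol, voi, discretize(vol, voi, bin_width)


class TestDiscretize:
    def test_floor_rule(self):
        _, _, reg = _region([0.0, 24.0, 25.0, 50.0])
        assert reg.levels.ravel().tolist() == [1, 1, 2, 3]
        assert reg.ng == 3

    def test_constant_region_single_level(self):
        _, _, reg = _region([7.0, 7.0, 7.0])
        assert reg.ng == 1

    def test_bad_bin_width(self):
        vol, voi, _ = _region([1.0, 2.0])
        with pytest.raises(ValueError, match="bin_width"):
            discretize(vol, voi, 0.0)


class TestFirstOrder:
    def test_symmetric_sample_has_zero_skewness(self):
        vol, voi, _ = _region([-1.0, 0.0, 1.0])
        assert first_order_features(vol, voi)["firstorder_Skewness"] == pytest.approx(0.0)

    def test_median_midpoint(self):
        vol, voi, _ = _region([1.0, 2.0, 3.0, 100.0])
        assert first_order_features(vol, voi)["firstorder_Median"] == pytest.approx(2.5)

    def test_constant_region_conventions(self):
        vol, voi, _ = _region([5.0] * 8)
        f = first_order_features(vol, voi)
        assert f["firstorder_Skewness"] == 0.0
        assert f["firstorder_Kurtosis"] == 0.0
        assert f["firstorder_Uniformity"] == 1.0


class TestGlcm:
    def test_constant_region(self):
        _, _, reg = _region(np.zeros((2, 2, 2)))
        f = glcm_features(reg)
        assert f["glcm_ClusterShade"] == pytest.approx(0.0)
        assert f["glcm_Idn"] == pytest.approx(1.0)
        assert f["glcm_Correlation"] == 1.0
        assert f["glcm_InverseVariance"] == 0.0

    def test_bounds(self, region_factory):
        for _ in range(5):
            vol, voi = region_factory()
            f = glcm_features(discretize(vol, voi, 25.0))
            assert f["glcm_InverseVariance"] >= 0.0
            assert 0.0 < f["glcm_Idn"] <= 1.0


class TestGlrlm:
    def test_single_run_long_run_emphasis(self):
        """A constant 1x1xN line: along the line it is a single run of length N
        (single-entry matrix, LRE = N^2); the 12 off-line directions each see N
        runs of length 1, and the direction average combines the two."""
        n = 6
        _, _, reg = _region(np.zeros((1, 1, n)))
        from acctex.texture import glrlm_matrix

        m = glrlm_matrix(reg, (0, 0, 1))
        assert m.shape == (1, n) and m[0, n - 1] == 1.0 and m.sum() == 1.0
        f = glrlm_features(reg)
        assert f["glrlm_LongRunEmphasis"] == pytest.approx((n * n + 12.0) / 13.0)
        assert f["glrlm_ShortRunEmphasis"] == pytest.approx((1.0 / n**2 + 12.0) / 13.0)
        assert f["glrlm_RunPercentage"] == pytest.approx((1.0 / n + 12.0) / 13.0)

    def test_alternating_levels_all_runs_length_one(self):
        vals = np.array([0.0, 100.0] * 4).reshape(1, 1, 8)
        _, _, reg = _region(vals)
        f = glrlm_features(reg)
        assert f["glrlm_ShortRunEmphasis"] == pytest.approx(1.0)
        assert f["glrlm_LongRunEmphasis"] == pytest.approx(1.0)


class TestGlszm:
    def test_constant_region_single_zone(self):
        _, _, reg = _region(np.zeros((2, 3, 2)))
        m = glszm_matrix(reg)
        assert m.shape == (1, 12) and m[0, -1] == 1.0

    def test_two_blobs_sizes_3_and_5(self):
        data = np.zeros((1, 1, 10))
        mask = np.zeros((1, 1, 10), dtype=bool)
        mask[0, 0, :3] = True   # blob of 3
        mask[0, 0, 5:] = True   # blob of 5, disjoint (gap at 3:5)
        _, _, reg = _region(data, mask=mask)
        m = glszm_matrix(reg)
        assert m[0, 2] == 1.0 and m[0, 4] == 1.0 and m.sum() == 2.0

    def test_all_distinct_levels_give_singleton_zones(self):
        data = (np.arange(64.0) * 25.0).reshape(4, 4, 4)
        _, _, reg = _region(data)
        m = glszm_matrix(reg)
        assert m.shape[1] == 1 and m.sum() == 64.0

    def test_checkerboard_connects_diagonally(self):
        """Under 26-connectivity a checkerboard's same-level voxels touch on
        diagonals, so each level forms a single 32-voxel zone."""
        zz, yy, xx = np.indices((4, 4, 4))
        data = ((zz + yy + xx) % 2) * 100.0
        _, _, reg = _region(data)
        m = glszm_matrix(reg)
        assert m.sum() == 2.0 and m[:, 31].sum() == 2.0


class TestGldm:
    def test_single_voxel_region(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        _, _, reg = _region(np.zeros((3, 3, 3)), mask=mask)
        f = gldm_features(reg)
        # dependence 0 -> column j=1, single entry
        assert f["gldm_LargeDependenceEmphasis"] == pytest.approx(1.0)
        assert f["gldm_DependenceVariance"] == pytest.approx(0.0)

    def test_constant_cube_brute_force(self):
        """On a constant 3^3 cube, per-voxel dependence counts are the in-bounds
        neighbor counts; DependenceVariance checked against direct enumeration."""
        _, _, reg = _region(np.zeros((3, 3, 3)))
        deps = []
        for z in range(3):
            for y in range(3):
                for x in range(3):
                    c = 0
                    for dz in (-1, 0, 1):
                        for dy in (-1, 0, 1):
                            for dx in (-1, 0, 1):
                                if (dz, dy, dx) == (0, 0, 0):
                                    continue
                                if 0 <= z + dz < 3 and 0 <= y + dy < 3 and 0 <= x + dx < 3:
                                    c += 1
                    deps.append(c + 1)  # column convention j = count + 1
        deps = np.array(deps, dtype=float)
        expected_var = np.mean((deps - deps.mean()) ** 2)
        f = gldm_features(reg)
        assert f["gldm_DependenceVariance"] == pytest.approx(expected_var)


class TestNgtdm:
    def test_constant_region_degenerate_zeros(self):
        _, _, reg = _region(np.zeros((2, 2, 2)))
        f = ngtdm_features(reg)
        assert f["ngtdm_Contrast"] == 0.0
        assert f["ngtdm_Busyness"] == 0.0

    def test_contrast_nonnegative(self, region_factory):
        for _ in range(5):
            vol, voi = region_factory()
            assert ngtdm_features(discretize(vol, voi, 25.0))["ngtdm_Contrast"] >= 0.0


def _phantom_case(phases=("venous",), seed=0, grade="low"):
    phase_data = {}
    for j, p in enumerate(phases):
        case, _ = generate_phantom(
            PhantomSpec(shape=(24, 24, 24), tumour_center=(12, 12, 8),
                        tumour_radii=(6, 6, 6), aorta_center_yx=(12, 20),
                        aorta_radius=2.0, phase=p, seed=seed + j),
            grade=grade,
        )
        phase_data[p] = case.phases[p]
    return StudyCase(case_id="t", phases=phase_data, grade=grade)


class TestExtractAll:
    def test_family_cardinalities(self, region_factory):
        vol, voi = region_factory()
        feats = extract_features(vol, voi, min_voxels=1)
        assert len(feats) == 92
        for family, names in FAMILY_NAMES.items():
            got = [k for k in feats if k.startswith(family + "_")]
            assert sorted(got) == sorted(names)
        assert {f: len(n) for f, n in FAMILY_NAMES.items()} == {
            "firstorder": 18, "glcm": 23, "glrlm": 16, "glszm": 16, "gldm": 14, "ngtdm": 5,
        }

    def test_row_counts_per_phase_and_voi(self):
        case4 = _phantom_case(("non-contrast", "arterial", "venous", "delayed"))
        case4 = VitalVoiBuilder().transform([case4])[0]
        table = extract_all(case4)
        assert len(table) == 8 and set(table.columns[5:]) == set(FEATURE_NAMES)
        case1 = VitalVoiBuilder().transform([_phantom_case()])[0]
        assert len(extract_all(case1)) == 2

    def test_determinism_identical_phases(self):
        case = _phantom_case()
        table = TextureExtractor().transform([case, case])
        rows = table[FEATURE_NAMES].to_numpy()
        np.testing.assert_array_equal(rows[0], rows[1])

    def test_subfloor_region_emits_missing(self):
        vol = Volume(np.zeros((3, 3, 3)), phase="venous")
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[0, 0, :2] = True
        feats = extract_features(vol, VOI(mask, kind="tumour-vital"), min_voxels=10)
        assert all(np.isnan(v) for v in feats.values())


class TestGridProperties:
    def test_rotation_invariance_direction_averaged_families(self, region_factory):
        """Axis-aligned 90-degree rotations permute the 13 directions, so
        direction-averaged GLCM/GLRLM features are unchanged."""
        vol, voi = region_factory()
        reg = discretize(vol, voi, 25.0)
        rot_vol = Volume(np.rot90(vol.data, axes=(1, 2)).copy(),
                         spacing=vol.spacing, phase="venous")
        rot_voi = VOI(np.rot90(voi.mask, axes=(1, 2)).copy(), kind="tumour-gross")
        rot = discretize(rot_vol, rot_voi, 25.0)
        for fn in (glcm_features, glrlm_features):
            a, b = fn(reg), fn(rot)
            for k in a:
                assert a[k] == pytest.approx(b[k], rel=1e-9), k

    def test_translation_invariance(self, rng):
        data = np.zeros((8, 8, 8))
        block = rng.normal(60, 30, (3, 3, 3))
        m1 = np.zeros((8, 8, 8), dtype=bool)
        m2 = np.zeros((8, 8, 8), dtype=bool)
        d1, d2 = data.copy(), data.copy()
        d1[0:3, 0:3, 0:3] = block
        m1[0:3, 0:3, 0:3] = True
        d2[4:7, 3:6, 2:5] = block
        m2[4:7, 3:6, 2:5] = True
        f1 = extract_features(Volume(d1, phase="venous"), VOI(m1, kind="tumour-gross"), min_voxels=1)
        f2 = extract_features(Volume(d2, phase="venous"), VOI(m2, kind="tumour-gross"), min_voxels=1)
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], rel=1e-12), k
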