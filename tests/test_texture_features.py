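"""Feature formulas, first-order statistics, shape features, extraction."""

import math

import numpy as np
import pytest

from myoradiomics.cohort import QuantitativeMap, RoiMask
from myoradiomics.features import (
    compute_glcm,
    extract_all,
    feature_registry,
    firstorder_features,
    shape2d_features,
)
from myoradiomics.features.matrices import compute_gldm, compute_glrlm, compute_glszm, compute_ngtdm
from myoradiomics.features.texture import (
    _GLDM_NAMES,
    _GLRLM_NAMES,
    _GLSZM_NAMES,
    gldm_features,
    glcm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)
from myoradiomics.preprocess import DiscretizationSpec, discretize_roi

from _feature_oracles import glcm_feats_bf, ngtdm_feats_bf, size_family_bf
from conftest import make_droi, random_droi


# ----------------------------------------------------------------- registry


def test_registry_inventory_counts():
    reg = feature_registry()
    assert len(reg) == 98
    by_class = {}
    for cls, _ in reg:
        by_class[cls] = by_class.get(cls, 0) + 1
    assert by_class == {
        "shape": 9,
        "firstorder": 16,
        "glcm": 22,
        "glrlm": 16,
        "glszm": 16,
        "gldm": 14,
        "ngtdm": 5,
    }
    assert len(feature_registry(include_shape=False)) == 89
    assert len(set(reg)) == 98  # no duplicate (class, name) pairs


# ---------------------------------------------------------- formula oracles


def test_glcm_features_match_loop_transcription():
    rng = np.random.default_rng(0)
    for _ in range(25):
        d = random_droi(rng)
        m = compute_glcm(d, 0)
        if m.degenerate:
            continue
        got = glcm_features(m)
        exp = glcm_feats_bf(m.values, m.n_levels)
        for name, val in exp.items():
            if math.isnan(val):
                assert math.isnan(got[name]), name
            else:
                assert got[name] == pytest.approx(val, abs=1e-9), name


@pytest.mark.parametrize("family", ["glrlm", "glszm", "gldm"])
def test_size_families_match_loop_transcription(family):
    rng = np.random.default_rng(1)
    build = {
        "glrlm": lambda d: compute_glrlm(d, 45),
        "glszm": compute_glszm,
        "gldm": compute_gldm,
    }[family]
    names = {"glrlm": _GLRLM_NAMES, "glszm": _GLSZM_NAMES, "gldm": _GLDM_NAMES}[family]
    feats = {
        "glrlm": glrlm_features,
        "glszm": glszm_features,
        "gldm": lambda m, n: gldm_features(m),
    }[family]
    for _ in range(25):
        d = random_droi(rng)
        m = build(d)
        n = int(d.mask.sum())
        got = feats(m, n)
        exp_generic = size_family_bf(m.values, n if family != "gldm" else int(m.values.sum()))
        for generic, label in names.items():
            assert got[label] == pytest.approx(exp_generic[generic], abs=1e-9), label


def test_ngtdm_features_match_loop_transcription():
    rng = np.random.default_rng(2)
    for _ in range(25):
        d = random_droi(rng)
        m = compute_ngtdm(d)
        if m.degenerate:
            continue
        got = ngtdm_features(m)
        exp = ngtdm_feats_bf(m.values[:, 0], m.values[:, 1], m.n_levels)
        for name, val in exp.items():
            if math.isnan(val):
                assert math.isnan(got[name]), name
            else:
                assert got[name] == pytest.approx(val, abs=1e-9), name


# --------------------------------------------------------- degenerate cases


def test_constant_roi_degenerate_glcm_features():
    d = make_droi(np.ones((4, 4), dtype=int))
    feats = glcm_features(compute_glcm(d, 0))
    assert feats["Contrast"] == 0.0
    assert feats["JointEnergy"] == 1.0
    assert math.isnan(feats["Correlation"])  # zero variance -> undefined


def test_constant_roi_ngtdm_contrast_zero_coarseness_undefined():
    d = make_droi(np.full((4, 4), 3, dtype=int))
    feats = ngtdm_features(compute_ngtdm(d))
    assert feats["Contrast"] == 0.0
    assert math.isnan(feats["Coarseness"])


def test_run_percentage_bounded():
    rng = np.random.default_rng(3)
    for _ in range(20):
        d = random_droi(rng)
        n = int(d.mask.sum())
        rp = glrlm_features(compute_glrlm(d, 0), n)["RunPercentage"]
        assert 0.0 < rp <= 1.0


def test_glcm_maximum_probability_from_two_row_matrix():
    d = make_droi([[1, 1], [2, 2]])
    assert glcm_features(compute_glcm(d, 0))["MaximumProbability"] == 0.5


# -------------------------------------------------------------- first order


def _roi_map(values_1d):
    """3-row replication so the ROI clears the 9-pixel minimum without
    changing Mean/Min/Max/Median."""
    arr = np.tile(np.asarray(values_1d, dtype=float), (3, 1))
    qmap = QuantitativeMap(arr, (1.0, 1.0), "T1", "fo")
    mask = RoiMask(np.ones(arr.shape, dtype=bool))
    d = discretize_roi(qmap, mask, DiscretizationSpec(1.0))
    return qmap, mask, d


def test_firstorder_basic_statistics():
    qmap, mask, d = _roi_map([1.0, 2.0, 3.0])
    f = firstorder_features(qmap, mask, d)
    assert f["Mean"] == 2.0
    assert f["Minimum"] == 1.0
    assert f["Maximum"] == 3.0
    assert f["Median"] == 2.0
    assert f["RootMeanSquared"] == pytest.approx(math.sqrt(14 / 3))
    assert f["Energy"] == pytest.approx(3 * (1 + 4 + 9))


def test_kurtosis_is_pearson_form():
    """Pearson kurtosis = excess kurtosis + 3 on any sample."""
    from scipy import stats as sps

    rng = np.random.default_rng(4)
    x = rng.normal(size=60)
    qmap, mask, d = _roi_map(x)
    f = firstorder_features(qmap, mask, d)
    excess = sps.kurtosis(np.tile(x, 3), fisher=True, bias=True)
    assert f["Kurtosis"] - excess == pytest.approx(3.0, abs=1e-9)
    skew = sps.skew(np.tile(x, 3), bias=True)
    assert f["Skewness"] == pytest.approx(skew, abs=1e-9)


def test_entropy_uniformity_two_equiprobable_levels():
    qmap, mask, d = _roi_map([1.0, 1.0, 2.0, 2.0])
    f = firstorder_features(qmap, mask, d)
    assert f["Uniformity"] == pytest.approx(0.5)
    assert f["Entropy"] == pytest.approx(1.0)  # 1 bit


def test_histogram_features_follow_bin_width_not_values():
    """Entropy responds to the discretization while Mean does not."""
    arr = np.tile(np.linspace(0, 100, 24), (3, 1))
    qmap = QuantitativeMap(arr, (1.0, 1.0), "T1", "fo")
    mask = RoiMask(np.ones(arr.shape, dtype=bool))
    fine = firstorder_features(qmap, mask, discretize_roi(qmap, mask, DiscretizationSpec(5.0)))
    coarse = firstorder_features(qmap, mask, discretize_roi(qmap, mask, DiscretizationSpec(50.0)))
    assert fine["Entropy"] > coarse["Entropy"]
    assert fine["Mean"] == coarse["Mean"]


# -------------------------------------------------------------------- shape


def test_square_roi_pixel_surface():
    mask = np.zeros((14, 14), dtype=bool)
    mask[2:12, 2:12] = True
    f = shape2d_features(RoiMask(mask), (1.0, 1.0))
    assert f["PixelSurface"] == 100.0
    assert f["MaximumDiameter"] == pytest.approx(9 * math.sqrt(2))


def test_sphericity_bounded_and_maximal_for_disk():
    rr, cc = np.mgrid[0:41, 0:41]
    disk = (rr - 20) ** 2 + (cc - 20) ** 2 <= 15**2
    square = np.zeros((41, 41), dtype=bool)
    square[5:25, 5:25] = True
    f_disk = shape2d_features(RoiMask(disk), (1.0, 1.0))
    f_square = shape2d_features(RoiMask(square), (1.0, 1.0))
    assert f_disk["Sphericity"] <= 1.0 + 0.01
    assert f_square["Sphericity"] < f_disk["Sphericity"]


def test_rectangle_elongation_matches_covariance_oracle():
    mask = np.zeros((10, 10), dtype=bool)
    mask[4:6, 3:8] = True  # 2 x 5 rectangle
    f = shape2d_features(RoiMask(mask), (2.0, 2.0))
    coords = np.argwhere(mask) * 2.0
    cov = np.cov(coords.T, ddof=0)
    eigs = np.sort(np.linalg.eigvalsh(cov))
    assert f["Elongation"] == pytest.approx(math.sqrt(eigs[0] / eigs[1]), abs=1e-9)
    assert f["MajorAxisLength"] == pytest.approx(4 * math.sqrt(eigs[1]), abs=1e-9)


def test_shape_ignores_intensities():
    rng = np.random.default_rng(5)
    mask = np.zeros((12, 12), dtype=bool)
    mask[3:9, 4:10] = True
    f1 = shape2d_features(RoiMask(mask), (1.5, 1.5))
    f2 = shape2d_features(RoiMask(mask.copy()), (1.5, 1.5))
    assert f1 == f2


# ---------------------------------------------------------------- extraction


def test_extract_counts_and_determinism(small_cohort):
    qmap, mask = small_cohort[0]
    recs = extract_all(qmap, mask, 2.1, 6.0)
    assert len(recs) == 98
    recs_f = extract_all(qmap, mask, 2.1, 6.0, filter_name="gradient")
    assert len(recs_f) == 89
    assert not any(r.feature_class == "shape" for r in recs_f)
    recs2 = extract_all(qmap, mask, 2.1, 6.0)
    assert recs == recs2


def test_extracted_records_carry_coordinate(small_cohort):
    qmap, mask = small_cohort[1]
    recs = extract_all(qmap, mask, 2.0, 5.0, filter_name="square")
    assert all(r.voxel_size_mm == 2.0 for r in recs)
    assert all(r.bin_width_ms == 5.0 for r in recs)
    assert all(r.filter_name == "square" for r in recs)
    assert {(r.feature_class, r.feature_name) for r in recs} == set(
        feature_registry(include_shape=False)
    )


def test_direction_averaged_features_invariant_under_rotation():
    """Rotating the ROI by 90 degrees leaves averaged GLCM/GLRLM features
    unchanged."""
    rng = np.random.default_rng(6)
    d = random_droi(rng, max_side=10, max_ng=5)
    r = make_droi(np.rot90(d.levels))
    from myoradiomics.features.engine import _texture_from_discretized

    f1 = _texture_from_discretized(d)
    f2 = _texture_from_discretized(r)
    for key, v1 in f1.items():
        v2 = f2[key]
        if math.isnan(v1):
            assert math.isnan(v2), key
        else:
            assert v1 == pytest.approx(v2, abs=1e-9), key
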