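"""Resampling, discretization and filter bank."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from myoradiomics.cohort import QuantitativeMap, RoiMask
from myoradiomics.preprocess import (
    FILTER_NAMES,
    DegenerateRoiError,
    DiscretizationSpec,
    FilterSpec,
    apply_filter,
    count_levels,
    discretize_roi,
    resample_map,
)

T1_BIN_WIDTHS = (3.60, 3.95, 4.30, 4.65, 5.00, 5.35, 5.70, 6.05, 6.40)


def _square_map(values, spacing=2.0):
    values = np.asarray(values, dtype=float)
    mask = np.ones(values.shape, dtype=bool)
    return QuantitativeMap(values, (spacing, spacing), "T1", "t"), RoiMask(mask)


# ---------------------------------------------------------------- resampling


def test_identity_resampling_reproduces_input():
    rng = np.random.default_rng(0)
    qmap, mask = _square_map(rng.normal(1000, 50, (10, 12)))
    out_map, out_mask = resample_map(qmap, mask, 2.0)
    assert out_map.values.shape == (10, 12)
    np.testing.assert_allclose(out_map.values, qmap.values, atol=1e-9)
    assert np.array_equal(out_mask.mask, mask.mask)


def test_constant_map_resamples_to_constant():
    qmap, mask = _square_map(np.full((9, 9), 700.0), spacing=2.3)
    out_map, _ = resample_map(qmap, mask, 1.8)
    np.testing.assert_allclose(out_map.values, 700.0, atol=1e-6)


def test_bspline_matches_independent_evaluation():
    """Every resampled grid point equals a direct tensor-product cubic
    B-spline evaluation (mirror boundary) at the physical coordinate."""
    from scipy import ndimage

    rng = np.random.default_rng(7)
    values = rng.normal(1000, 60, (8, 8))
    qmap, mask = _square_map(values, spacing=2.0)
    out_map, _ = resample_map(qmap, mask, 2.1)
    nr, nc = out_map.values.shape
    rr, cc = np.mgrid[0:nr, 0:nc]
    expected = ndimage.map_coordinates(
        values, [rr * 2.1 / 2.0, cc * 2.1 / 2.0], order=3, mode="mirror"
    )
    np.testing.assert_allclose(out_map.values, expected, atol=1e-9)
    assert out_map.values[3, 3] == pytest.approx(expected[3, 3], abs=1e-9)


def test_bspline_reproduces_ramp_away_from_boundary():
    """Deep inside the grid the cubic spline of a linear field is linear
    (boundary prefilter effects decay geometrically)."""
    rows, cols = np.mgrid[0:24, 0:24]
    values = 10.0 * rows + 3.0 * cols + 500.0  # in index units, spacing 2.0
    qmap, mask = _square_map(values, spacing=2.0)
    out_map, _ = resample_map(qmap, mask, 2.1)
    r = c = 11
    expected = 10.0 * (r * 2.1 / 2.0) + 3.0 * (c * 2.1 / 2.0) + 500.0
    assert out_map.values[r, c] == pytest.approx(expected, abs=1e-6)


def test_resampling_changes_grid_size():
    qmap, mask = _square_map(np.zeros((100, 100)), spacing=2.0)
    out_map, _ = resample_map(qmap, mask, 1.8)
    assert out_map.values.shape == (111, 111)
    assert out_map.spacing_mm == (1.8, 1.8)


def test_degenerate_roi_after_resampling_raises():
    values = np.zeros((40, 40))
    mask = np.zeros((40, 40), dtype=bool)
    mask[20:23, 20:23] = True  # 9 px at 1 mm collapses below 9 px at 5 mm
    qmap = QuantitativeMap(values, (1.0, 1.0), "T1", "t")
    with pytest.raises(DegenerateRoiError):
        resample_map(qmap, RoiMask(mask), 5.0)


# ------------------------------------------------------------ discretization


def _discretize_values(vals, w, anchor="multiples-of-W"):
    vals = np.asarray(vals, dtype=float).reshape(1, -1)
    pad = np.tile(vals, (9, 1))  # RoiMask needs >= 9 px; replicate rows
    qmap = QuantitativeMap(pad, (1.0, 1.0), "T1", "t")
    mask = RoiMask(np.ones(pad.shape, dtype=bool))
    d = discretize_roi(qmap, mask, DiscretizationSpec(w, anchor))
    return d.levels[0], d.n_levels


@pytest.mark.parametrize(
    "vals,w,levels,ng",
    [
        ([0.0, 1.0, 2.0, 3.0], 1.0, [1, 2, 3, 4], 4),
        ([5.0, 5.0, 5.0, 5.0], 2.0, [1, 1, 1, 1], 1),
        ([5.5, 6.1, 9.9], 2.0, [1, 2, 3], 3),
    ],
)
def test_discretization_examples(vals, w, levels, ng):
    got, got_ng = _discretize_values(vals, w)
    assert list(got) == levels
    assert got_ng == ng


def test_roi_minimum_anchoring():
    got, ng = _discretize_values([5.5, 6.1, 9.9], 2.0, anchor="roi-minimum")
    assert list(got) == [1, 1, 3]
    assert ng == 3


@settings(max_examples=50, deadline=None)
@given(
    # dyadic values and widths keep floor() exact under the shift
    vals=st.lists(st.integers(0, 8000).map(lambda n: n * 0.25), min_size=2, max_size=12),
    w=st.sampled_from([0.5, 1.0, 2.0, 4.0]),
    c=st.integers(-5, 5),
)
def test_discretization_shift_equivariance(vals, w, c):
    """Adding an integer multiple of W to all values leaves levels unchanged."""
    base, _ = _discretize_values(vals, w)
    shifted, _ = _discretize_values([v + c * w for v in vals], w)
    assert list(base) == list(shifted)


@settings(max_examples=30, deadline=None)
@given(vals=st.lists(st.floats(0, 500, allow_nan=False), min_size=3, max_size=10))
def test_level_count_nonincreasing_in_bin_width(vals):
    ngs = [_discretize_values(vals, w)[1] for w in (1.0, 2.0, 4.0, 8.0)]
    assert all(a >= b for a, b in zip(ngs, ngs[1:]))


def test_discretization_monotone_in_value():
    got, _ = _discretize_values([1.0, 3.0, 3.0, 7.9, 12.0], 2.5)
    assert all(a <= b for a, b in zip(got, got[1:]))


# ----------------------------------------------------------------- level counts


def test_count_levels_phase_maximal_example():
    assert count_levels(10.0, [5.0], phase="max") == [3]
    assert count_levels(10.0, [5.0], phase="min") == [3]  # exact multiple
    assert count_levels(10.1, [5.0], phase="min") == [3]
    assert count_levels(10.1, [5.0], phase="max") == [4]


def test_count_levels_zero_range():
    assert count_levels(0.0, [5.0]) == [1]


def test_t1_bin_widths_keep_level_counts_in_30_130():
    for phase in ("min", "max"):
        counts = count_levels(265.0, T1_BIN_WIDTHS, phase=phase)
        assert all(30 <= c <= 130 for c in counts)


def test_t2_bin_widths_keep_level_counts_in_30_130():
    t2 = [0.49, 0.50, 0.51, 0.52, 0.53, 0.54, 0.55, 0.56, 0.57]
    for phase in ("min", "max"):
        counts = count_levels(26.0, t2, phase=phase)
        assert all(30 <= c <= 130 for c in counts)


# --------------------------------------------------------------------- filters


def test_square_and_square_root_literal_algebra():
    qmap, _ = _square_map(np.array([[2.0, -4.0, 9.0]] * 3))
    literal = lambda n: FilterSpec(n, intensity_rescale=False)
    assert apply_filter(qmap, literal("square")).values[0, 0] == 4.0
    assert apply_filter(qmap, literal("square-root")).values[0, 1] == 2.0
    assert apply_filter(qmap, FilterSpec("original")).values[0, 2] == 9.0


def test_square_rescale_preserves_intensity_range():
    """The default square/square-root filters map the maximum absolute
    intensity onto itself, so fixed millisecond bin widths stay usable."""
    rng = np.random.default_rng(6)
    qmap, _ = _square_map(rng.uniform(900, 1165, (10, 10)))
    for name in ("square", "square-root"):
        out = apply_filter(qmap, FilterSpec(name)).values
        assert out.max() == pytest.approx(np.abs(qmap.values).max())
        # level count at the fixed 6 ms T1 bin width stays moderate
        n_levels = count_levels(float(out.max() - out.min()), [6.0])[0]
        assert n_levels < 200


def test_high_pass_filters_annihilate_constants():
    qmap, _ = _square_map(np.full((16, 16), 123.0))
    for name in ("gradient", "wavelet-LH", "wavelet-HL", "wavelet-HH"):
        out = apply_filter(qmap, FilterSpec(name)).values
        np.testing.assert_allclose(out, 0.0, atol=1e-9)


def test_gradient_of_ramp_has_exact_interior_magnitude():
    rows = np.mgrid[0:10, 0:12][0].astype(float)
    qmap, _ = _square_map(7.0 * rows, spacing=2.0)  # slope 3.5 ms/mm along rows
    out = apply_filter(qmap, FilterSpec("gradient")).values
    np.testing.assert_allclose(out[1:-1, :], 3.5, atol=1e-12)


def test_wavelet_subbands_reconstruct_input():
    import pywt

    rng = np.random.default_rng(1)
    values = rng.normal(1000, 80, (16, 16))
    qmap, _ = _square_map(values)
    from myoradiomics.preprocess import _swt_subbands

    bands = _swt_subbands(values, "db3")
    rec = pywt.iswtn([bands], "db3", axes=(0, 1))
    np.testing.assert_allclose(rec, values, atol=1e-6)


def test_wavelet_on_odd_grid_is_congruent_and_finite():
    rng = np.random.default_rng(2)
    qmap, _ = _square_map(rng.normal(50, 5, (13, 17)))
    for name in FILTER_NAMES:
        out = apply_filter(qmap, FilterSpec(name)).values
        assert out.shape == (13, 17)
        assert np.all(np.isfinite(out))


def test_unknown_filter_rejected():
    qmap, _ = _square_map(np.zeros((9, 9)))
    with pytest.raises(ValueError, match="unknown filter"):
        apply_filter(qmap, FilterSpec("laplacian"))
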