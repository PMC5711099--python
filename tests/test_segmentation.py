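import numpy as np
import pytest

from mtvbench import (
    BinaryMask,
    GbmParams,
    ImageGrid,
    LesionSpec,
    PhantomSpec,
    RoiBox,
    SuvVolume,
    connected_component_filter,
    deconvolve,
    denoise_edge_preserving,
    generate_phantom,
    mask_volume_ml,
    reference_uptake,
    segment_fixed_threshold,
    segment_flab,
    segment_gbm,
    segment_relative_threshold,
)
from mtvbench.segmentation import MAX_VOXEL, NEIGHBORHOOD_MEAN5, flab_fit_means


def full_roi(grid: ImageGrid) -> RoiBox:
    lo, hi = grid.bounding_box()
    return RoiBox(tuple(lo), tuple(hi))


# ---------------------------------------------------------------------------
# reference uptake dialects
# ---------------------------------------------------------------------------

def test_reference_uptake_flat_region():
    g = ImageGrid((6, 6, 6), (4, 4, 4))
    vol = SuvVolume(g, np.full(g.shape, 3.3))
    roi = full_roi(g)
    assert reference_uptake(vol, roi, MAX_VOXEL) == 3.3
    assert reference_uptake(vol, roi, NEIGHBORHOOD_MEAN5) == pytest.approx(3.3)


def test_reference_uptake_single_hot_voxel():
    g = ImageGrid((7, 7, 7), (4, 4, 4))
    vals = np.ones(g.shape)
    vals[3, 3, 3] = 10.0
    vol = SuvVolume(g, vals)
    roi = full_roi(g)
    assert reference_uptake(vol, roi, MAX_VOXEL) == 10.0
    assert reference_uptake(vol, roi, NEIGHBORHOOD_MEAN5) == pytest.approx(2.8)


def test_reference_uptake_mean5_never_exceeds_max():
    rng = np.random.default_rng(0)
    g = ImageGrid((8, 8, 8), (4, 4, 4))
    roi = full_roi(g)
    for _ in range(25):
        vol = SuvVolume(g, rng.uniform(0, 10, g.shape))
        assert reference_uptake(vol, roi, NEIGHBORHOOD_MEAN5) <= reference_uptake(
            vol, roi, MAX_VOXEL
        )


def test_reference_uptake_hot_voxel_at_corner_uses_what_exists():
    g = ImageGrid((5, 5, 5), (4, 4, 4))
    vals = np.ones(g.shape)
    vals[0, 0, 0] = 10.0
    vol = SuvVolume(g, vals)
    assert reference_uptake(vol, full_roi(g), NEIGHBORHOOD_MEAN5) == pytest.approx(2.8)


def test_reference_uptake_empty_roi_errors(plateau_case):
    with pytest.raises(ValueError):
        reference_uptake(plateau_case.pet, RoiBox((300, 300, 300), (400, 400, 400)))


# ---------------------------------------------------------------------------
# threshold arms and component filtering
# ---------------------------------------------------------------------------

def test_fixed_threshold_simple_values():
    g = ImageGrid((4, 4, 4), (4, 4, 4))
    vals = np.ones(g.shape)
    vals[1, 1, 1], vals[1, 1, 2], vals[1, 2, 1] = 3.0, 10.0, 2.0
    vol = SuvVolume(g, vals)
    mask = segment_fixed_threshold(vol, full_roi(g), 2.5)
    expected = np.zeros(g.shape, bool)
    expected[1, 1, 1] = expected[1, 1, 2] = True
    assert np.array_equal(mask.member, expected)


def test_fixed_threshold_all_background_empty(pet_grid):
    vol = SuvVolume(pet_grid, np.ones(pet_grid.shape))
    mask = segment_fixed_threshold(vol, full_roi(pet_grid), 2.5)
    assert not mask.member.any()


def test_threshold_recovers_plateau_truth(plateau_case):
    m = segment_fixed_threshold(plateau_case.pet, plateau_case.roi, 2.5)
    assert np.array_equal(m.member, plateau_case.truth.member)
    m45 = segment_relative_threshold(plateau_case.pet, plateau_case.roi, 0.45)
    assert np.array_equal(m45.member, plateau_case.truth.member)


def test_dialects_agree_on_homogeneous_plateau(plateau_case):
    a = segment_relative_threshold(plateau_case.pet, plateau_case.roi, 0.45, MAX_VOXEL)
    b = segment_relative_threshold(
        plateau_case.pet, plateau_case.roi, 0.45, NEIGHBORHOOD_MEAN5
    )
    assert np.array_equal(a.member, b.member)


def test_mean5_mask_contains_max_voxel_mask(noisy_case):
    # lower reference => lower threshold => superset
    a = segment_relative_threshold(noisy_case.pet, noisy_case.roi, 0.45, MAX_VOXEL)
    b = segment_relative_threshold(
        noisy_case.pet, noisy_case.roi, 0.45, NEIGHBORHOOD_MEAN5
    )
    assert np.all(b.member | ~a.member)


def test_threshold_monotonicity(noisy_case):
    m3 = segment_fixed_threshold(noisy_case.pet, noisy_case.roi, 3.0)
    m25 = segment_fixed_threshold(noisy_case.pet, noisy_case.roi, 2.5)
    assert np.all(m25.member | ~m3.member)


def test_component_filter_keeps_hot_blob():
    g = ImageGrid((12, 12, 4), (4, 4, 4))
    vals = np.ones(g.shape)
    vals[1:3, 1:3, 1] = 4.0   # cool blob
    vals[8:10, 8:10, 1] = 9.0  # hot blob
    mem = vals >= 2.5
    vol = SuvVolume(g, vals)
    out = connected_component_filter(BinaryMask(g, mem), vol, full_roi(g))
    assert out.member[9, 9, 1]
    assert not out.member[1, 1, 1]
    # single component passes through unchanged
    single = np.zeros(g.shape, bool)
    single[4:6, 4:6, 1:3] = True
    out2 = connected_component_filter(BinaryMask(g, single), vol, full_roi(g))
    assert np.array_equal(out2.member, single)
    # empty in, empty out
    empty = BinaryMask(g, np.zeros(g.shape, bool))
    assert not connected_component_filter(empty, vol, full_roi(g)).member.any()


def test_masks_restricted_to_roi(noisy_case):
    roi = noisy_case.roi
    roi_arr = roi.grid_mask(noisy_case.pet.grid)
    for mask in (
        segment_fixed_threshold(noisy_case.pet, roi, 2.5),
        segment_relative_threshold(noisy_case.pet, roi, 0.45),
        segment_flab(noisy_case.pet, roi),
        segment_gbm(noisy_case.pet, roi),
    ):
        assert not np.any(mask.member & ~roi_arr)


def test_confounder_excluded_by_roi():
    g = ImageGrid((30, 30, 20), (4, 4, 4))
    spec = PhantomSpec(
        lesions=(LesionSpec((40.0, 40.0, 40.0), (10.0, 10.0, 10.0), 8.0),),
        confounders=(LesionSpec((100.0, 100.0, 40.0), (10.0, 10.0, 10.0), 12.0),),
        pet_grid=g, psf_fwhm=0.0, noise_sd_at_background=0.0, roi_margin_mm=12.0,
    )
    case = generate_phantom(spec)
    m = segment_fixed_threshold(case.pet, case.roi, 2.5)
    assert np.array_equal(m.member, case.truth.member)


# ---------------------------------------------------------------------------
# FLAB
# ---------------------------------------------------------------------------

def test_flab_recovers_two_class_parameters():
    rng = np.random.default_rng(42)
    shape = (24, 24, 24)
    ii, jj, kk = np.indices(shape)
    labels = ((ii - 12) ** 2 + (jj - 12) ** 2 + (kk - 12) ** 2) <= 8**2
    x = np.where(labels, rng.normal(8, 0.5, shape), rng.normal(1, 0.5, shape))
    mu0, mu1, mask = flab_fit_means(np.maximum(x, 0))
    assert abs(mu0 - 1.0) / 1.0 < 0.05
    assert abs(mu1 - 8.0) / 8.0 < 0.05
    assert np.mean(mask == labels) >= 0.98


def test_flab_exact_on_noiseless_plateau(plateau_case):
    m = segment_flab(plateau_case.pet, plateau_case.roi)
    assert np.array_equal(m.member, plateau_case.truth.member)


def test_flab_tumor_is_higher_mean_class(noisy_case):
    m = segment_flab(noisy_case.pet, noisy_case.roi)
    inside = noisy_case.pet.values[m.member]
    outside = noisy_case.pet.values[noisy_case.roi.grid_mask(noisy_case.pet.grid) & ~m.member]
    assert inside.mean() > outside.mean()


def test_flab_degenerate_roi_errors():
    g = ImageGrid((6, 6, 6), (4, 4, 4))
    vol = SuvVolume(g, np.full(g.shape, 2.0))
    with pytest.raises(ValueError, match="degenerate"):
        segment_flab(vol, full_roi(g))


def test_flab_requires_minimum_roi():
    g = ImageGrid((2, 2, 2), (4, 4, 4))
    vol = SuvVolume(g, np.random.default_rng(0).uniform(1, 2, g.shape))
    with pytest.raises(ValueError, match="20 voxels"):
        segment_flab(vol, full_roi(g))


# ---------------------------------------------------------------------------
# denoise / deconvolve building blocks
# ---------------------------------------------------------------------------

def test_bilateral_constant_unchanged():
    g = ImageGrid((8, 8, 8), (4, 4, 4))
    vol = SuvVolume(g, np.full(g.shape, 4.2))
    out = denoise_edge_preserving(vol)
    assert np.allclose(out.values, 4.2)


def test_bilateral_bounded_and_edge_preserving():
    g = ImageGrid((20, 6, 6), (4, 4, 4))
    vals = np.where(np.arange(20)[:, None, None] < 10, 1.0, 8.0) * np.ones(g.shape)
    noisy = vals + np.random.default_rng(0).normal(0, 0.1, g.shape)
    noisy = np.maximum(noisy, 0)
    out = denoise_edge_preserving(SuvVolume(g, noisy), 4.0, 0.5)
    assert out.values.min() >= noisy.min() - 1e-9
    assert out.values.max() <= noisy.max() + 1e-9
    # midpoint crossing of the step stays within one voxel of the true edge
    profile = out.values[:, 3, 3]
    crossing = np.argmax(profile > 4.5)
    assert abs(crossing - 10) <= 1


def test_deconvolve_identity_cases():
    g = ImageGrid((10, 10, 10), (4, 4, 4))
    vals = np.random.default_rng(1).uniform(0, 5, g.shape)
    vol = SuvVolume(g, vals)
    assert np.array_equal(deconvolve(vol, 0.0, 10).values, vals)
    assert np.array_equal(deconvolve(vol, 7.0, 0).values, vals)


def test_deconvolve_resharpens_and_conserves():
    g = ImageGrid((16, 16, 16), (4, 4, 4))
    from scipy import ndimage

    point = np.zeros(g.shape)
    point[8, 8, 8] = 100.0
    sigma = 7.0 / 2.3548 / 4.0
    blurred = ndimage.gaussian_filter(point, sigma, mode="reflect")
    out = deconvolve(SuvVolume(g, blurred), 7.0, 10)
    assert out.values.max() >= blurred.max()
    assert out.values.min() >= 0
    assert abs(out.values.sum() - blurred.sum()) / blurred.sum() < 0.01


# ---------------------------------------------------------------------------
# GBM
# ---------------------------------------------------------------------------

def test_gbm_exact_on_two_plateau_image(plateau_case):
    m = segment_gbm(plateau_case.pet, plateau_case.roi, GbmParams(psf_fwhm=0.0))
    assert np.array_equal(m.member, plateau_case.truth.member)


def test_gbm_blurred_sphere_volume_within_25pct():
    g = ImageGrid((32, 32, 32), (4, 4, 4))
    spec = PhantomSpec(
        lesions=(LesionSpec((60.0, 60.0, 60.0), (15.0, 15.0, 15.0), 5.0),),
        pet_grid=g, background_suv=0.625, psf_fwhm=7.0, noise_sd_at_background=0.0,
    )
    case = generate_phantom(spec)
    m = segment_gbm(case.pet, case.roi, GbmParams(psf_fwhm=7.0))
    v = mask_volume_ml(m)
    analytic = spec.lesions[0].analytic_volume_ml
    assert abs(v - analytic) / analytic < 0.25


def test_gbm_hottest_voxel_always_in_mask(noisy_case):
    m = segment_gbm(noisy_case.pet, noisy_case.roi)
    sl = noisy_case.roi.index_slices(noisy_case.pet.grid)
    sub = noisy_case.pet.values[sl]
    local = np.unravel_index(int(np.argmax(sub)), sub.shape)
    idx = tuple(local[a] + sl[a].start for a in range(3))
    assert m.member[idx]


def test_gbm_single_basin_errors():
    g = ImageGrid((8, 8, 8), (4, 4, 4))
    vol = SuvVolume(g, np.full(g.shape, 2.0))
    with pytest.raises(ValueError, match="basin"):
        segment_gbm(vol, full_roi(g), GbmParams(psf_fwhm=0.0))


# ---------------------------------------------------------------------------
# cross-arm properties
# ---------------------------------------------------------------------------

def test_all_arms_exact_on_noiseless_plateau(plateau_case):
    truth = plateau_case.truth.member
    for mask in (
        segment_fixed_threshold(plateau_case.pet, plateau_case.roi, 2.5),
        segment_relative_threshold(plateau_case.pet, plateau_case.roi, 0.45, MAX_VOXEL),
        segment_relative_threshold(
            plateau_case.pet, plateau_case.roi, 0.45, NEIGHBORHOOD_MEAN5
        ),
        segment_flab(plateau_case.pet, plateau_case.roi),
        segment_gbm(plateau_case.pet, plateau_case.roi, GbmParams(psf_fwhm=0.0)),
    ):
        assert np.array_equal(mask.member, truth)


def test_rel45_nested_in_suv25_when_threshold_higher(noisy_case):
    ref = reference_uptake(noisy_case.pet, noisy_case.roi, MAX_VOXEL)
    if 0.45 * ref >= 2.5:
        rel = segment_relative_threshold(noisy_case.pet, noisy_case.roi, 0.45)
        fixed = segment_fixed_threshold(noisy_case.pet, noisy_case.roi, 2.5)
        assert np.all(fixed.member | ~rel.member)
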