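import numpy as np
import pytest

from mtvbench import (
    CohortRanges,
    ImageGrid,
    LesionSpec,
    PhantomSpec,
    generate_cohort,
    generate_phantom,
    make_ct_grid,
    mask_volume_ml,
    suv_stats,
)
from mtvbench.phantom import DEFAULT_PET_GRID, save_cohort_specs, load_cohort_specs


def brute_force_sphere_voxels(grid, center, radius):
    cx, cy, cz = grid.voxel_centers()
    count = 0
    for i in range(grid.dims[0]):
        for j in range(grid.dims[1]):
            for k in range(grid.dims[2]):
                d2 = (cx[i] - center[0]) ** 2 + (cy[j] - center[1]) ** 2 + (cz[k] - center[2]) ** 2
                if d2 <= radius**2:
                    count += 1
    return count


def test_plateau_sphere_values_and_truth_volume(plateau_case):
    vals = np.unique(plateau_case.pet.values)
    assert set(vals) == {1.0, 8.0}
    # rasterized truth counts exactly the voxel centers inside the sphere
    n = brute_force_sphere_voxels(plateau_case.pet.grid, (40, 40, 40), 10.0)
    assert int(plateau_case.truth.member.sum()) == n
    # and sits within one boundary-voxel layer of the analytic 4.19 ml
    v = mask_volume_ml(plateau_case.truth)
    assert abs(v - 4.19) < 1.5


def test_r15_sphere_rasterization_matches_brute_force():
    g = ImageGrid((32, 32, 32), (4, 4, 4))
    # generic (non-lattice-aligned) center: voxel-center counting tracks the
    # analytic 14.14 ml closely; lattice-aligned centers can deviate by >10%
    # through integer-point count fluctuations
    center = (61.0, 61.0, 61.0)
    spec = PhantomSpec(
        lesions=(LesionSpec(center, (15.0, 15.0, 15.0), 8.0),),
        pet_grid=g, psf_fwhm=0.0, noise_sd_at_background=0.0,
    )
    case = generate_phantom(spec)
    analytic = spec.lesions[0].analytic_volume_ml
    assert analytic == pytest.approx(14.137, abs=0.01)
    n = brute_force_sphere_voxels(g, center, 15.0)
    assert int(case.truth.member.sum()) == n
    assert abs(mask_volume_ml(case.truth) - analytic) / analytic < 0.05


def test_noise_only_changes_values_not_truth(pet_grid):
    base = dict(
        lesions=(LesionSpec((40.0, 40.0, 40.0), (10.0, 10.0, 10.0), 8.0),),
        pet_grid=pet_grid, psf_fwhm=0.0, noise_sd_at_background=0.2,
    )
    a = generate_phantom(PhantomSpec(**base, seed=1))
    b = generate_phantom(PhantomSpec(**base, seed=2))
    assert np.array_equal(a.truth.member, b.truth.member)
    assert not np.array_equal(a.pet.values, b.pet.values)
    # same seed: bit-identical
    c = generate_phantom(PhantomSpec(**base, seed=1))
    assert np.array_equal(a.pet.values, c.pet.values)


def test_unblurred_homogeneous_suvmax_is_plateau(plateau_case):
    smax, smean = suv_stats(plateau_case.pet, plateau_case.truth)
    assert smax == 8.0
    assert smean == 8.0


def test_blur_conserves_total_signal(pet_grid):
    spec = PhantomSpec(
        lesions=(LesionSpec((40.0, 40.0, 40.0), (10.0, 10.0, 10.0), 8.0),),
        pet_grid=pet_grid, psf_fwhm=7.0, noise_sd_at_background=0.0,
    )
    blurred = generate_phantom(spec)
    sharp = generate_phantom(
        PhantomSpec(
            lesions=spec.lesions, pet_grid=pet_grid, psf_fwhm=0.0,
            noise_sd_at_background=0.0,
        )
    )
    s0 = sharp.pet.values.sum()
    s1 = blurred.pet.values.sum()
    assert abs(s1 - s0) / s0 < 0.005


def test_lesion_outside_grid_rejected(pet_grid):
    spec = PhantomSpec(
        lesions=(LesionSpec((500.0, 500.0, 500.0), (5.0, 5.0, 5.0), 8.0),),
        pet_grid=pet_grid,
    )
    with pytest.raises(ValueError, match="outside"):
        generate_phantom(spec)


def test_confounder_must_be_outside_roi(pet_grid):
    spec = PhantomSpec(
        lesions=(LesionSpec((40.0, 40.0, 40.0), (10.0, 10.0, 10.0), 8.0),),
        confounders=(LesionSpec((44.0, 44.0, 44.0), (6.0, 6.0, 6.0), 12.0),),
        pet_grid=pet_grid,
    )
    with pytest.raises(ValueError, match="confounder"):
        generate_phantom(spec)


def test_cohort_reproducible_and_sized():
    a = generate_cohort(8, seed=5)
    b = generate_cohort(8, seed=5)
    assert len(a) == 8
    assert [c.case_id for c in a] == [f"case{i:03d}" for i in range(8)]
    for ca, cb in zip(a, b):
        assert ca.spec == cb.spec
        assert np.array_equal(ca.pet.values, cb.pet.values)


def test_cohort_volumes_match_lognormal_mean():
    # sample mean of analytic volumes vs the truncated-lognormal expectation,
    # estimated independently by direct Monte Carlo of the generator's draw
    ranges = CohortRanges()
    n = 400
    cases_vols = []
    rng = np.random.default_rng(1)
    mu, sd = np.log(ranges.volume_median_ml), ranges.volume_log_sd
    lo, hi = ranges.volume_bounds_ml
    oracle = np.clip(np.exp(rng.normal(mu, sd, 200_000)), lo, hi).mean()
    cases = generate_cohort(n, ranges, seed=1)
    vols = np.array([c.spec.lesions[0].analytic_volume_ml for c in cases])
    se = vols.std(ddof=1) / np.sqrt(n)
    assert abs(vols.mean() - oracle) < 2 * se + 0.05 * oracle
    assert vols.min() >= lo - 1e-9 and vols.max() <= hi + 1e-9


def test_cohort_contrast_and_heterogeneity_ranges():
    ranges = CohortRanges(contrast_range=(3.0, 10.0), heterogeneous_fraction=0.5)
    cases = generate_cohort(40, ranges, seed=2)
    ups = np.array([c.spec.lesions[0].uptake for c in cases])
    assert ups.min() >= 3.0 * ranges.background_suv
    assert ups.max() <= 10.0 * ranges.background_suv
    het = np.mean([c.spec.lesions[0].heterogeneity_sd > 0 for c in cases])
    assert 0.2 < het < 0.8


def test_degenerate_ranges_give_exact_spec():
    ranges = CohortRanges(
        volume_median_ml=10.0, volume_log_sd=0.0, volume_bounds_ml=(10.0, 10.001),
        contrast_range=(5.0, 5.0), heterogeneous_fraction=0.0, aspect_log_sd=0.0,
    )
    (case,) = generate_cohort(1, ranges, seed=9)
    lesion = case.spec.lesions[0]
    assert lesion.uptake == pytest.approx(5.0)
    assert lesion.analytic_volume_ml == pytest.approx(10.0, rel=1e-3)
    assert lesion.semiaxes[0] == pytest.approx(lesion.semiaxes[1])


def test_invalid_ranges_rejected():
    with pytest.raises(ValueError):
        CohortRanges(volume_bounds_ml=(10.0, 4.0))
    with pytest.raises(ValueError):
        generate_cohort(0)


@pytest.mark.parametrize(
    "kind,spacing", [("fine", (0.59, 0.59, 3.0)), ("coarse", (1.17, 1.17, 3.0))]
)
def test_ct_grid_spacing_and_coverage(kind, spacing):
    ct = make_ct_grid(kind)
    assert ct.spacing == spacing
    pet_lo, pet_hi = DEFAULT_PET_GRID.bounding_box()
    ct_lo, ct_hi = ct.bounding_box()
    assert np.all(ct_lo <= pet_lo + 1e-9)
    assert np.all(ct_hi >= pet_hi - 1e-9)
    with pytest.raises(ValueError):
        make_ct_grid("medium")


def test_spec_json_roundtrip(tmp_path, noisy_case):
    path = tmp_path / "cohort.json"
    save_cohort_specs([noisy_case], path)
    (back,) = load_cohort_specs(path)
    assert back.spec == noisy_case.spec
    assert np.array_equal(back.pet.values, noisy_case.pet.values)
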