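"""Synthetic PET/CT phantom cohort generator.

Each phantom emulates one patient of a rectal-cancer PET delineation study:
an ellipsoidal lesion of known (ground-truth) extent painted in SUV units on
a 4 mm isotropic PET grid, blurred by the scanner point-spread function,
degraded with intensity-dependent reconstruction-like noise, and optionally
accompanied by a bladder-like hot confounder outside the analysis box. A
companion planning-CT grid (fine 0.59x0.59x3 mm or coarse 1.17x1.17x3 mm)
is provided for resampling experiments.

The ground-truth mask is the pre-blur ellipsoid rasterized at voxel centers;
it plays the role a reference tumor volume plays in a clinical comparison.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage

from .volumes import BinaryMask, ImageGrid, RoiBox, SuvVolume

DEFAULT_PET_GRID = ImageGrid(dims=(36, 36, 36), spacing=(4.0, 4.0, 4.0))

#: In-plane matrix / spacing of the two planning-CT conventions.
CT_GRID_SPACINGS = {
    "fine": (0.59, 0.59, 3.0),
    "coarse": (1.17, 1.17, 3.0),
}


@dataclass(frozen=True)
class LesionSpec:
    """One ellipsoidal uptake region.

    ``uptake`` is the plateau SUV before blur; ``heterogeneity_sd`` adds
    spatially correlated intra-lesion variation (SUV standard deviation)
    with correlation length ``texture_scale`` mm.
    """

    center: tuple[float, float, float]
    semiaxes: tuple[float, float, float]
    uptake: float
    heterogeneity_sd: float = 0.0
    texture_scale: float = 8.0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semiaxes):
            raise ValueError("semiaxes must be positive")
        if self.uptake <= 0:
            raise ValueError("uptake must be positive")
        if self.heterogeneity_sd < 0:
            raise ValueError("heterogeneity_sd must be >= 0")

    @property
    def analytic_volume_ml(self) -> float:
        a, b, c = self.semiaxes
        return 4.0 / 3.0 * np.pi * a * b * c / 1000.0


@dataclass(frozen=True)
class PhantomSpec:
    """Generative description of one synthetic patient."""

    lesions: tuple[LesionSpec, ...]
    pet_grid: ImageGrid = DEFAULT_PET_GRID
    background_suv: float = 1.0
    confounders: tuple[LesionSpec, ...] = ()
    psf_fwhm: float = 7.0
    noise_sd_at_background: float = 0.1
    roi_margin_mm: float = 16.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.psf_fwhm < 0:
            raise ValueError("psf_fwhm must be >= 0")
        if self.noise_sd_at_background < 0:
            raise ValueError("noise sd must be >= 0")
        if self.background_suv < 0:
            raise ValueError("background SUV must be >= 0")
        if not self.lesions:
            raise ValueError("at least one lesion is required")


@dataclass
class PhantomCase:
    """One realized phantom: SUV volume, ground-truth mask and analysis box."""

    spec: PhantomSpec
    pet: SuvVolume
    truth: BinaryMask
    roi: RoiBox
    case_id: str = ""


def _ellipsoid_mask(grid: ImageGrid, lesion: LesionSpec) -> np.ndarray:
    cx, cy, cz = grid.voxel_centers()
    c = lesion.center
    a = lesion.semiaxes
    dx = ((cx - c[0]) / a[0]) ** 2
    dy = ((cy - c[1]) / a[1]) ** 2
    dz = ((cz - c[2]) / a[2]) ** 2
    return dx[:, None, None] + dy[None, :, None] + dz[None, None, :] <= 1.0


def _correlated_texture(
    shape: tuple[int, ...], spacing: tuple[float, ...], scale_mm: float, sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Smoothed white noise rescaled to a target pointwise SD."""
    white = rng.standard_normal(shape)
    if scale_mm <= 0:
        return white * sd
    sigma_vox = [scale_mm / s for s in spacing]
    smooth = ndimage.gaussian_filter(white, sigma_vox, mode="reflect")
    s = smooth.std()
    return smooth * (sd / s) if s > 0 else smooth


def derive_roi(spec: PhantomSpec) -> RoiBox:
    """Analysis box: lesion bounding box plus a margin, clipped to the grid.

    The margin (default 16 mm) leaves room for blur spill-out and for
    background sampling while excluding confounder structures, mimicking the
    physician's exclusion of physiological uptake.
    """
    lo = np.min(
        [np.asarray(l.center, float) - np.asarray(l.semiaxes, float) for l in spec.lesions],
        axis=0,
    )
    hi = np.max(
        [np.asarray(l.center, float) + np.asarray(l.semiaxes, float) for l in spec.lesions],
        axis=0,
    )
    lo -= spec.roi_margin_mm
    hi += spec.roi_margin_mm
    gmin, gmax = spec.pet_grid.bounding_box()
    lo = np.maximum(lo, gmin)
    hi = np.minimum(hi, gmax)
    return RoiBox(tuple(lo), tuple(hi))


def generate_phantom(spec: PhantomSpec, case_id: str = "") -> PhantomCase:
    """Realize one phantom from its spec (deterministic given the seed).

    Pipeline: paint background, add lesion plateaus plus correlated texture
    (clipped at 0), add confounders, convolve with the isotropic Gaussian
    PSF (reflective padding, normalized kernel), add Gaussian noise whose
    variance scales with the local mean (normalized so the background SD
    equals ``noise_sd_at_background``), and clip at 0.
    """
    grid = spec.pet_grid
    rng = np.random.default_rng(spec.seed)
    img = np.full(grid.shape, float(spec.background_suv))
    truth = np.zeros(grid.shape, dtype=bool)

    for lesion in spec.lesions:
        inside = _ellipsoid_mask(grid, lesion)
        if not inside.any():
            raise ValueError(f"lesion at {lesion.center} lies fully outside the grid")
        vals = np.full(grid.shape, float(lesion.uptake))
        if lesion.heterogeneity_sd > 0:
            vals = vals + _correlated_texture(
                grid.shape, grid.spacing, lesion.texture_scale,
                lesion.heterogeneity_sd, rng,
            )
            vals = np.maximum(vals, 0.0)
        img[inside] = vals[inside]
        truth |= inside

    roi = derive_roi(spec)
    for conf in spec.confounders:
        if roi.contains(np.asarray(conf.center))[0]:
            raise ValueError("confounder center must lie outside the RoiBox")
        inside = _ellipsoid_mask(grid, conf)
        img[inside] = conf.uptake

    if spec.psf_fwhm > 0:
        sigma_vox = [spec.psf_fwhm / 2.3548200450309493 / s for s in grid.spacing]
        img = ndimage.gaussian_filter(img, sigma_vox, mode="reflect")

    if spec.noise_sd_at_background > 0:
        local = np.maximum(img, 0.0)
        ref = spec.background_suv if spec.background_suv > 0 else 1.0
        sd = spec.noise_sd_at_background * np.sqrt(local / ref)
        img = img + rng.standard_normal(grid.shape) * sd

    img = np.maximum(img, 0.0)
    return PhantomCase(spec, SuvVolume(grid, img), BinaryMask(grid, truth), roi, case_id)


@dataclass(frozen=True)
class CohortRanges:
    """Sampling ranges for a synthetic cohort.

    Lesion analytic volumes are log-normal (median ``volume_median_ml``,
    log-SD ``volume_log_sd``), truncated to ``volume_bounds_ml`` so the
    cohort spans roughly the 4-120 ml clinical range. Lesion-to-background
    contrast is uniform; a stated fraction of lesions carries correlated
    uptake heterogeneity.
    """

    volume_median_ml: float = 20.0
    volume_log_sd: float = 0.85
    volume_bounds_ml: tuple[float, float] = (4.0, 120.0)
    contrast_range: tuple[float, float] = (3.0, 10.0)
    heterogeneous_fraction: float = 0.5
    heterogeneity_rel_sd: float = 0.15
    aspect_log_sd: float = 0.15
    background_suv: float = 1.0
    psf_fwhm: float = 7.0
    noise_sd_at_background: float = 0.1
    add_confounder: bool = True

    def __post_init__(self) -> None:
        if self.volume_bounds_ml[0] >= self.volume_bounds_ml[1]:
            raise ValueError("volume bounds must be an increasing pair")
        if self.contrast_range[0] > self.contrast_range[1]:
            raise ValueError("contrast range must be ordered")
        if not 0 <= self.heterogeneous_fraction <= 1:
            raise ValueError("heterogeneous_fraction must be in [0,1]")


def _sample_spec(
    ranges: CohortRanges, grid: ImageGrid, rng: np.random.Generator, seed: int
) -> PhantomSpec:
    lo, hi = ranges.volume_bounds_ml
    mu = np.log(ranges.volume_median_ml)
    vol = float(np.exp(rng.normal(mu, ranges.volume_log_sd)))
    vol = min(max(vol, lo), hi)
    # semiaxes: equivalent-sphere radius modulated by a volume-preserving
    # anisotropy factor
    r_eq = (3.0 * vol * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    q = np.exp(rng.normal(0.0, ranges.aspect_log_sd, size=3))
    q /= q.prod() ** (1.0 / 3.0)
    semiaxes = tuple(float(r_eq * qi) for qi in q)

    gmin, gmax = grid.bounding_box()
    center_grid = (np.asarray(gmin) + np.asarray(gmax)) / 2.0
    jitter = rng.uniform(-4.0, 4.0, size=3)
    center = tuple(float(c) for c in center_grid + jitter)

    contrast = float(rng.uniform(*ranges.contrast_range))
    uptake = ranges.background_suv * contrast
    heterogeneous = rng.uniform() < ranges.heterogeneous_fraction
    het_sd = ranges.heterogeneity_rel_sd * uptake if heterogeneous else 0.0
    lesion = LesionSpec(center, semiaxes, uptake, heterogeneity_sd=het_sd)

    confounders: tuple[LesionSpec, ...] = ()
    if ranges.add_confounder:
        # bladder-like hot sphere near a grid corner, outside the RoiBox
        conf_center = tuple(float(v) for v in np.asarray(gmax) - 14.0)
        confounders = (
            LesionSpec(conf_center, (12.0, 12.0, 10.0), 10.0 * ranges.background_suv),
        )

    return PhantomSpec(
        lesions=(lesion,),
        pet_grid=grid,
        background_suv=ranges.background_suv,
        confounders=confounders,
        psf_fwhm=ranges.psf_fwhm,
        noise_sd_at_background=ranges.noise_sd_at_background,
        seed=seed,
    )


def generate_cohort(
    n: int = 31,
    ranges: CohortRanges | None = None,
    seed: int = 0,
    pet_grid: ImageGrid = DEFAULT_PET_GRID,
) -> list[PhantomCase]:
    """Generate a reproducible cohort of ``n`` phantom patients.

    The default cohort size matches a typical single-center delineation
    study (31 patients). Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    ranges = ranges or CohortRanges()
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n):
        case_seed = int(rng.integers(0, 2**31 - 1))
        spec = _sample_spec(ranges, pet_grid, rng, case_seed)
        cases.append(generate_phantom(spec, case_id=f"case{i:03d}"))
    return cases


def make_ct_grid(kind: str = "fine", pet_grid: ImageGrid = DEFAULT_PET_GRID) -> ImageGrid:
    """Planning-CT grid ('fine' 0.59x0.59x3 mm or 'coarse' 1.17x1.17x3 mm)
    covering the PET extent."""
    if kind not in CT_GRID_SPACINGS:
        raise ValueError(f"unknown CT grid kind {kind!r}; use 'fine' or 'coarse'")
    spacing = CT_GRID_SPACINGS[kind]
    lo, hi = pet_grid.bounding_box()
    dims = tuple(
        int(np.ceil((hi[a] - lo[a]) / spacing[a])) for a in range(3)
    )
    origin = tuple(float(lo[a] + spacing[a] / 2.0) for a in range(3))
    return ImageGrid(dims, spacing, origin)


def spec_to_dict(spec: PhantomSpec) -> dict:
    """JSON-serializable representation of a phantom spec."""
    d = asdict(spec)
    d["pet_grid"] = {
        "dims": list(spec.pet_grid.dims),
        "spacing": list(spec.pet_grid.spacing),
        "origin": list(spec.pet_grid.origin),
    }
    return d


def spec_from_dict(d: dict) -> PhantomSpec:
    g = d["pet_grid"]
    grid = ImageGrid(tuple(g["dims"]), tuple(g["spacing"]), tuple(g["origin"]))
    lesions = tuple(LesionSpec(tuple(l["center"]), tuple(l["semiaxes"]), l["uptake"],
                               l.get("heterogeneity_sd", 0.0), l.get("texture_scale", 8.0))
                    for l in d["lesions"])
    confs = tuple(LesionSpec(tuple(l["center"]), tuple(l["semiaxes"]), l["uptake"],
                             l.get("heterogeneity_sd", 0.0), l.get("texture_scale", 8.0))
                  for l in d.get("confounders", ()))
    return PhantomSpec(
        lesions=lesions, pet_grid=grid,
        background_suv=d["background_suv"], confounders=confs,
        psf_fwhm=d["psf_fwhm"], noise_sd_at_background=d["noise_sd_at_background"],
        roi_margin_mm=d.get("roi_margin_mm", 16.0), seed=d["seed"],
    )


def save_cohort_specs(cases: list[PhantomCase], path) -> None:
    payload = [
        {"case_id": c.case_id, **spec_to_dict(c.spec)} for c in cases
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def load_cohort_specs(path) -> list[PhantomCase]:
    with open(path) as fh:
        payload = json.load(fh)
    return [generate_phantom(spec_from_dict(d), case_id=d.get("case_id", "")) for d in payload]
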