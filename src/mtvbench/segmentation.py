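"""PET tumor delineation algorithms.

Six arms are modeled, mirroring what clinical workstations offer:

* absolute SUV threshold (voxels with SUV >= 2.5), under either
  reference-uptake dialect label;
* relative threshold at 45% of the reference uptake, where the reference is
  either the single hottest voxel ("max_voxel") or the average of the
  hottest voxel and its four hottest neighbors ("neighborhood_mean5" — the
  behavior of workstations that average five pixels around the maximum);
* a fuzzy locally adaptive Bayesian classifier (two hard intensity classes
  plus fuzzy transition levels with spatially local label priors);
* a gradient-based method: edge-preserving denoising, iterative
  Richardson-Lucy deconvolution, watershed of the gradient magnitude, and
  two-cluster grouping of the basins.

Every arm is a deterministic function of (volume, ROI box, configuration)
and returns a mask restricted to the ROI, cleaned by a connected-component
filter seeded at the hottest ROI voxel (the physician's exclusion of
physiological uptake reduced to a reproducible rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import local_minima
from skimage.segmentation import watershed

from .volumes import BinaryMask, RoiBox, SuvVolume, mask_volume_ml, suv_stats

MAX_VOXEL = "max_voxel"
NEIGHBORHOOD_MEAN5 = "neighborhood_mean5"
_DIALECTS = (MAX_VOXEL, NEIGHBORHOOD_MEAN5)

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class FlabParams:
    n_fuzzy_levels: int = 3
    max_iter: int = 100
    tol: float = 1e-3  # converged when this fraction of labels still changes

    def __post_init__(self) -> None:
        if self.n_fuzzy_levels < 0 or self.max_iter < 1:
            raise ValueError("invalid FLAB parameters")


@dataclass(frozen=True)
class GbmParams:
    denoise_spatial_sigma_mm: float = 4.0
    denoise_range_sigma_suv: float = 0.5
    decon_iters: int = 10
    psf_fwhm: float = 7.0
    n_clusters: int = 2

    def __post_init__(self) -> None:
        if self.decon_iters < 0 or self.psf_fwhm < 0:
            raise ValueError("invalid GBM parameters")


@dataclass(frozen=True)
class SegMethodConfig:
    """Configuration for one delineation arm."""

    method: str  # fixed_threshold | relative_threshold | flab | gbm
    label: str = ""
    absolute_suv: float = 2.5
    fraction: float = 0.45
    dialect: str = MAX_VOXEL
    flab_params: FlabParams = field(default_factory=FlabParams)
    gbm_params: GbmParams = field(default_factory=GbmParams)

    def __post_init__(self) -> None:
        if self.method not in ("fixed_threshold", "relative_threshold", "flab", "gbm"):
            raise ValueError(f"unknown method {self.method!r}")
        if not 0 < self.fraction < 1:
            raise ValueError("fraction must be in (0,1)")
        if self.absolute_suv <= 0:
            raise ValueError("absolute_suv must be positive")
        if self.dialect not in _DIALECTS:
            raise ValueError(f"unknown dialect {self.dialect!r}")
        if not self.label:
            object.__setattr__(self, "label", self.method)


@dataclass
class SegmentationResult:
    """Mask plus the volume/SUV summary a comparison study tabulates."""

    label: str
    mask: BinaryMask
    suv_max: float
    suv_mean: float
    volume_ml: float


def _hottest_roi_index(vol: SuvVolume, roi: RoiBox) -> tuple[int, int, int]:
    sl = roi.index_slices(vol.grid)
    sub = vol.values[sl]
    if sub.size == 0:
        raise ValueError("ROI contains no voxels")
    flat = int(np.argmax(sub))
    local = np.unravel_index(flat, sub.shape)
    return tuple(int(local[a] + sl[a].start) for a in range(3))


def reference_uptake(vol: SuvVolume, roi: RoiBox, dialect: str = MAX_VOXEL) -> float:
    """Reference uptake used by relative thresholding.

    ``max_voxel``: the maximum SUV in the ROI. ``neighborhood_mean5``: the
    mean of the hottest ROI voxel and its 4 hottest 26-neighbors (fewer at
    an image edge). The latter never exceeds the former.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    idx = _hottest_roi_index(vol, roi)
    vmax = float(vol.values[idx])
    if dialect == MAX_VOXEL:
        return vmax
    neigh = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if di == dj == dk == 0:
                    continue
                p = (idx[0] + di, idx[1] + dj, idx[2] + dk)
                if all(0 <= p[a] < vol.grid.dims[a] for a in range(3)):
                    neigh.append(float(vol.values[p]))
    neigh.sort(reverse=True)
    top = neigh[:4]
    return float(np.mean([vmax] + top))


def connected_component_filter(mask: BinaryMask, vol: SuvVolume, roi: RoiBox) -> BinaryMask:
    """Keep the 26-connected component holding the hottest masked ROI voxel.

    Removes disconnected physiological-uptake islands. An empty mask passes
    through unchanged.
    """
    if not mask.member.any():
        return mask
    labels, _ = ndimage.label(mask.member, structure=_CONN26)
    roi_mask = roi.grid_mask(mask.grid)
    seedable = mask.member & roi_mask
    if not seedable.any():
        seedable = mask.member
    vals = np.where(seedable, vol.values, -np.inf)
    seed = np.unravel_index(int(np.argmax(vals)), vals.shape)
    keep = labels == labels[seed]
    return BinaryMask(mask.grid, keep)


def segment_fixed_threshold(
    vol: SuvVolume, roi: RoiBox, absolute_suv: float = 2.5
) -> BinaryMask:
    """Absolute threshold: ROI voxels with SUV >= ``absolute_suv``."""
    member = (vol.values >= absolute_suv) & roi.grid_mask(vol.grid)
    return connected_component_filter(BinaryMask(vol.grid, member), vol, roi)


def segment_relative_threshold(
    vol: SuvVolume, roi: RoiBox, fraction: float = 0.45, dialect: str = MAX_VOXEL
) -> BinaryMask:
    """Relative threshold: ROI voxels with SUV >= fraction x reference uptake."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0,1)")
    t = fraction * reference_uptake(vol, roi, dialect)
    member = (vol.values >= t) & roi.grid_mask(vol.grid)
    return connected_component_filter(BinaryMask(vol.grid, member), vol, roi)


# ---------------------------------------------------------------------------
# Fuzzy locally adaptive Bayesian classification
# ---------------------------------------------------------------------------

def _kmeans2_1d(x: np.ndarray, max_iter: int = 100) -> tuple[float, float, float, float]:
    """Deterministic 1-D two-means: returns (mu0, sigma0, mu1, sigma1), mu0 < mu1."""
    # min/max init keeps a small high-uptake class from being swallowed by
    # a dominant background class
    c0, c1 = float(x.min()), float(x.max())
    if c0 == c1:
        raise ValueError("ROI intensities are degenerate (constant)")
    for _ in range(max_iter):
        assign = np.abs(x - c1) < np.abs(x - c0)
        if assign.all() or (~assign).all():
            break
        n0, n1 = float(x[~assign].mean()), float(x[assign].mean())
        if n0 == c0 and n1 == c1:
            break
        c0, c1 = n0, n1
    assign = np.abs(x - c1) < np.abs(x - c0)
    if assign.all() or (~assign).all():
        raise ValueError("ROI intensities are degenerate (single class)")
    mu0, mu1 = float(x[~assign].mean()), float(x[assign].mean())
    s0, s1 = float(x[~assign].std()), float(x[assign].std())
    if mu0 > mu1:
        mu0, mu1, s0, s1 = mu1, mu0, s1, s0
    return mu0, s0, mu1, s1


def segment_flab(
    vol: SuvVolume, roi: RoiBox, params: FlabParams | None = None
) -> BinaryMask:
    """Fuzzy locally adaptive Bayesian segmentation of the ROI.

    Two hard Gaussian classes (background, tumor) are augmented with
    ``n_fuzzy_levels`` partial-volume levels whose means and variances
    interpolate linearly between the hard classes (mixing fraction
    eps = l/(n+1)). Voxels are iteratively reassigned to the level with the
    largest local posterior, the prior of a level at a voxel being its
    frequency among the 26-neighbor labels (uniform at the first pass).
    Class means/variances are re-estimated with fuzzy voxels contributing
    (1-eps) to the background class and eps to the tumor class. The tumor
    mask collects hard-tumor voxels plus fuzzy voxels with eps >= 0.5.

    The tumor class is, by convention, the higher-mean class, which breaks
    label symmetry. Deterministic given its inputs.
    """
    params = params or FlabParams()
    sl = roi.index_slices(vol.grid)
    x = vol.values[sl]
    if x.size < 20:
        raise ValueError("FLAB needs an ROI of at least 20 voxels")
    if np.ptp(x) == 0:
        raise ValueError("ROI intensities are degenerate (constant)")

    mu0, s0, mu1, s1 = _kmeans2_1d(x.ravel())
    nf = params.n_fuzzy_levels
    eps = np.concatenate([[0.0], np.arange(1, nf + 1) / (nf + 1), [1.0]])
    nlev = eps.size

    labels = np.zeros(x.shape, dtype=np.int8)
    var_floor = max(1e-12, 1e-6 * (mu1 - mu0) ** 2)
    neigh_kernel = _CONN26.astype(float).copy()
    neigh_kernel[1, 1, 1] = 0.0
    n_neigh = ndimage.correlate(np.ones(x.shape), neigh_kernel, mode="constant")

    for it in range(params.max_iter):
        means = (1 - eps) * mu0 + eps * mu1
        varis = np.maximum((1 - eps) * s0**2 + eps * s1**2, var_floor)
        loglik = np.stack(
            [
                -0.5 * np.log(2 * np.pi * varis[l]) - (x - means[l]) ** 2 / (2 * varis[l])
                for l in range(nlev)
            ]
        )
        if it == 0:
            logprior = np.zeros_like(loglik)
        else:
            counts = np.stack(
                [
                    ndimage.correlate(
                        (labels == l).astype(float), neigh_kernel, mode="constant"
                    )
                    for l in range(nlev)
                ]
            )
            prior = (counts + 1e-6) / (n_neigh + nlev * 1e-6)
            logprior = np.log(prior)
        new_labels = np.argmax(logprior + loglik, axis=0).astype(np.int8)
        changed = float(np.mean(new_labels != labels))
        labels = new_labels

        w1 = eps[labels]
        w0 = 1.0 - w1
        sw0, sw1 = w0.sum(), w1.sum()
        if sw0 > 0:
            mu0 = float((w0 * x).sum() / sw0)
            s0 = float(np.sqrt((w0 * (x - mu0) ** 2).sum() / sw0))
        if sw1 > 0:
            mu1 = float((w1 * x).sum() / sw1)
            s1 = float(np.sqrt((w1 * (x - mu1) ** 2).sum() / sw1))
        if mu0 > mu1:
            mu0, mu1, s0, s1 = mu1, mu0, s1, s0
            labels = (nlev - 1 - labels).astype(np.int8)
        if it > 0 and changed < params.tol:
            break

    member = np.zeros(vol.grid.shape, dtype=bool)
    member[sl] = eps[labels] >= 0.5
    return connected_component_filter(BinaryMask(vol.grid, member), vol, roi)


def flab_fit_means(
    values: np.ndarray, params: FlabParams | None = None
) -> tuple[float, float, np.ndarray]:
    """Run the FLAB iteration on a raw 3-D array; return (mu0, mu1, tumor mask).

    Convenience entry point for validating class-parameter recovery on
    synthetic two-class fields without grid bookkeeping.
    """
    from .volumes import ImageGrid

    values = np.asarray(values, dtype=float)
    grid = ImageGrid(values.shape, (1.0, 1.0, 1.0))
    vol = SuvVolume(grid, np.maximum(values, 0.0))
    lo, hi = grid.bounding_box()
    roi = RoiBox(tuple(lo), tuple(hi))
    mask = segment_flab(vol, roi, params)
    inside = vol.values[mask.member]
    outside = vol.values[~mask.member]
    return float(outside.mean()), float(inside.mean()), mask.member


# ---------------------------------------------------------------------------
# Gradient-based method (denoise -> deconvolve -> watershed -> cluster)
# ---------------------------------------------------------------------------

def denoise_edge_preserving(
    vol: SuvVolume, spatial_sigma_mm: float = 4.0, range_sigma_suv: float = 0.5
) -> SuvVolume:
    """3-D bilateral filter: Gaussian spatial kernel weighted by a Gaussian
    penalty on the intensity difference, so plateaus smooth but edges hold."""
    if spatial_sigma_mm <= 0:
        return SuvVolume(vol.grid, vol.values.copy())
    v = vol.values
    spacing = vol.grid.spacing
    radii = [max(1, min(3, int(np.ceil(2 * spatial_sigma_mm / s)))) for s in spacing]
    num = np.zeros_like(v)
    den = np.zeros_like(v)
    inv2ss = 1.0 / (2 * spatial_sigma_mm**2)
    inv2rs = 1.0 / (2 * range_sigma_suv**2)
    for di in range(-radii[0], radii[0] + 1):
        for dj in range(-radii[1], radii[1] + 1):
            for dk in range(-radii[2], radii[2] + 1):
                d2 = (di * spacing[0]) ** 2 + (dj * spacing[1]) ** 2 + (dk * spacing[2]) ** 2
                ws = np.exp(-d2 * inv2ss)
                shifted = np.roll(v, (-di, -dj, -dk), axis=(0, 1, 2))
                # roll wraps around; mask out wrapped slabs so borders use
                # only genuine neighbors
                valid = np.ones_like(v, dtype=bool)
                for ax, d in enumerate((di, dj, dk)):
                    if d > 0:
                        sl = [slice(None)] * 3
                        sl[ax] = slice(v.shape[ax] - d, None)
                        valid[tuple(sl)] = False
                    elif d < 0:
                        sl = [slice(None)] * 3
                        sl[ax] = slice(0, -d)
                        valid[tuple(sl)] = False
                wr = np.exp(-((shifted - v) ** 2) * inv2rs)
                w = ws * wr * valid
                num += w * shifted
                den += w
    return SuvVolume(vol.grid, num / den)


def deconvolve(vol: SuvVolume, psf_fwhm: float, iters: int = 10) -> SuvVolume:
    """Richardson-Lucy deconvolution with an isotropic Gaussian PSF.

    With ``psf_fwhm = 0`` or ``iters = 0`` this is the identity. Output is
    non-negative and (for interior structures) conserves total signal.
    """
    if psf_fwhm <= 0 or iters <= 0:
        return SuvVolume(vol.grid, vol.values.copy())
    sigma_vox = [psf_fwhm / 2.3548200450309493 / s for s in vol.grid.spacing]

    def blur(a: np.ndarray) -> np.ndarray:
        return ndimage.gaussian_filter(a, sigma_vox, mode="reflect")

    d = np.maximum(vol.values, 0.0)
    u = d.copy()
    tiny = 1e-12
    for _ in range(iters):
        conv = blur(u)
        ratio = d / np.maximum(conv, tiny)
        u = u * blur(ratio)  # Gaussian PSF is symmetric: adjoint = forward
    return SuvVolume(vol.grid, np.maximum(u, 0.0))


def _gradient_magnitude(values: np.ndarray, spacing: tuple[float, ...]) -> np.ndarray:
    g = np.gradient(values, *spacing)
    return np.sqrt(sum(gi**2 for gi in g))


def segment_gbm(
    vol: SuvVolume, roi: RoiBox, params: GbmParams | None = None
) -> BinaryMask:
    """Gradient-based delineation within the ROI.

    Pipeline: bilateral denoising, Richardson-Lucy deconvolution, gradient
    magnitude (central differences, spacing-aware), watershed with basins
    seeded at the regional minima of the gradient image, then agglomerative
    grouping of basins by mean denoised intensity (closest cluster means
    merged, voxel-count-weighted) until two clusters remain. The tumor is
    the cluster holding the hottest ROI voxel. Deterministic.
    """
    params = params or GbmParams()
    sl = roi.index_slices(vol.grid)
    sub = vol.values[sl]
    from .volumes import ImageGrid

    sub_grid = ImageGrid(
        sub.shape,
        vol.grid.spacing,
        tuple(vol.grid.origin[a] + sl[a].start * vol.grid.spacing[a] for a in range(3)),
    )
    den = denoise_edge_preserving(
        SuvVolume(sub_grid, sub),
        params.denoise_spatial_sigma_mm,
        params.denoise_range_sigma_suv,
    )
    dec = deconvolve(den, params.psf_fwhm, params.decon_iters)
    grad = _gradient_magnitude(dec.values, vol.grid.spacing)

    # face connectivity: central differences leave diagonal gaps in the
    # gradient shell, so 26-connected minima would leak across the edge
    conn6 = ndimage.generate_binary_structure(3, 1)
    minima = local_minima(grad, connectivity=1, allow_borders=True)
    markers, n_basins = ndimage.label(minima, structure=conn6)
    if n_basins < 2:
        raise ValueError("ROI contains a single gradient basin; no separable structure")
    basins = watershed(grad, markers=markers, connectivity=conn6)

    # agglomerate basins on mean denoised intensity until n_clusters remain
    ids = np.arange(1, n_basins + 1)
    sums = ndimage.sum_labels(den.values, basins, ids)
    counts = ndimage.sum_labels(np.ones_like(den.values), basins, ids)
    clusters = [
        {"basins": [int(i)], "sum": float(s), "n": float(c)}
        for i, s, c in zip(ids, sums, counts)
    ]
    while len(clusters) > params.n_clusters:
        means = [c["sum"] / c["n"] for c in clusters]
        order = np.argsort(means, kind="stable")
        gaps = [means[order[j + 1]] - means[order[j]] for j in range(len(order) - 1)]
        j = int(np.argmin(gaps))
        a, b = int(order[j]), int(order[j + 1])
        keep, drop = min(a, b), max(a, b)
        clusters[keep] = {
            "basins": clusters[keep]["basins"] + clusters[drop]["basins"],
            "sum": clusters[keep]["sum"] + clusters[drop]["sum"],
            "n": clusters[keep]["n"] + clusters[drop]["n"],
        }
        del clusters[drop]

    hot = np.unravel_index(int(np.argmax(sub)), sub.shape)
    hot_basin = int(basins[hot])
    tumor = next(c for c in clusters if hot_basin in c["basins"])
    member_sub = np.isin(basins, tumor["basins"])

    member = np.zeros(vol.grid.shape, dtype=bool)
    member[sl] = member_sub
    return connected_component_filter(BinaryMask(vol.grid, member), vol, roi)


def run_arm(vol: SuvVolume, roi: RoiBox, cfg: SegMethodConfig) -> SegmentationResult:
    """Run one configured delineation arm and summarize volume and SUV."""
    if cfg.method == "fixed_threshold":
        mask = segment_fixed_threshold(vol, roi, cfg.absolute_suv)
    elif cfg.method == "relative_threshold":
        mask = segment_relative_threshold(vol, roi, cfg.fraction, cfg.dialect)
    elif cfg.method == "flab":
        mask = segment_flab(vol, roi, cfg.flab_params)
    else:
        mask = segment_gbm(vol, roi, cfg.gbm_params)
    if mask.member.any():
        smax, smean = suv_stats(vol, mask)
    else:
        smax = smean = float("nan")
    return SegmentationResult(cfg.label, mask, smax, smean, mask_volume_ml(mask))
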