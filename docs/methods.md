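# Methods

## Coordinate and unit conventions

All positions are patient millimetres on axis-aligned grids. Voxel
`(i, j, k)` has its center at `origin + index · spacing` and occupies the
half-open box `[center − spacing/2, center + spacing/2)`; this single
convention drives rasterization, contour extraction and the round-trip
identity (`voxel_edge` export + `center_inside` import on the source grid
is exact by construction). PET intensities are SUV (dimensionless);
conversion from raw activity is out of scope — phantoms are generated
directly in SUV. Volumes are reported in ml (voxel count × voxel volume).

## Synthetic phantom model

Each case is built as: background plateau → ellipsoidal lesion plateau(s),
optionally plus spatially correlated Gaussian texture (smoothed white
noise, correlation length `texture_scale`, clipped at 0) → optional
confounder lesions (bladder-like hot structures outside the analysis box)
→ isotropic Gaussian PSF blur (FWHM `psf_fwhm`, reflective padding,
normalized kernel — total signal is conserved to <0.5% for interior
lesions) → voxelwise Gaussian noise with SD ∝ √(local mean), normalized so
the background SD equals `noise_sd_at_background` → clip at 0. The
ground-truth mask is the **pre-blur** ellipsoid rasterized at voxel
centers; it plays the role a clinical reference volume plays in an
agreement study.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| PET grid | 36³ voxels, 4×4×4 mm | clinical whole-body PET voxel size; extent 144 mm comfortably holds the largest cohort lesion plus blur margin |
| CT grids | 0.59×0.59×3 mm ("fine"), 1.17×1.17×3 mm ("coarse") | the two planning-CT reconstruction conventions modeled |
| background SUV | 1.0 | soft-tissue background scale |
| cohort volumes | log-normal, median 20 ml, log-SD 0.85, truncated to 4–120 ml | spans the clinical MTV range with the right skew |
| contrast | uniform 3:1–10:1 | typical tumor-to-background ratios |
| heterogeneous fraction | 0.5, texture SD = 0.15 × uptake, 8 mm correlation length | half the cohort carries realistic intra-lesion variation |
| PSF FWHM | 7 mm | whole-body PET reconstruction resolution |
| noise SD at background | 0.1 SUV | ~10% background noise, a mid-range reconstruction level; no scanner-specific claim is made |
| ROI margin | 16 mm around the lesion bounding box | room for blur spill-out and background sampling while excluding confounders |

The noise model is Gaussian with variance proportional to the local mean —
a standard approximation to reconstructed-PET noise — rather than raw
Poisson counts; no sinogram/TOF reconstruction chain is simulated. The
analysis box (`RoiBox`) stands in for the physician's manual exclusion of
physiological uptake; it is derived from the phantom geometry, and no
claim is made about replicating human ROI placement.

**What passing tests on these phantoms show**: that the algorithms,
metrics and transfer mechanisms behave correctly and with the documented
signs and orderings under controlled conditions. **What they do not
show**: clinical accuracy. Real rectal-cancer PET has organ motion,
non-ellipsoidal shapes, far richer texture, and reconstruction artifacts;
published per-patient magnitudes are specific to such data and are
reproduced here only as sign/ordering properties.

## Segmentation arms

*Reference uptake dialects.* `max_voxel` is the hottest ROI voxel.
`neighborhood_mean5` averages the hottest voxel with its 4 hottest
26-neighbors (3-D; fewer at an image edge), emulating workstations that
average five pixels around the maximum. The neighborhood is taken in 3-D
because slice-restricted behavior is not observable from the outside; the
choice is recorded, not claimed as any vendor's exact kernel.

*Thresholds.* Comparisons use ≥ ("equal or superior"). After thresholding,
a connected-component filter keeps only the 26-connected component holding
the hottest masked ROI voxel, removing islands of physiological uptake.
Threshold masks are monotone (higher threshold ⊆ lower threshold), which
survives the component filter because connectivity is inherited by
subsets containing the seed.

*FLAB.* ROI intensities are modeled with two hard Gaussian classes
(background, tumor) plus `n_fuzzy_levels` (default 3) partial-volume
levels with means `(1−ε)μ₀ + εμ₁` and variances `(1−ε)σ₀² + εσ₁²`,
ε = l/(n+1). Initialization is a deterministic 1-D two-means with min/max
centers (percentile initialization collapses when the tumor occupies ~1%
of the ROI box, the normal geometry here). Each iteration classifies every
voxel to the level maximizing the local posterior — the prior of a level
at a voxel is its frequency among the 26-neighbor labels (uniform on the
first pass, with a 1e-6 additive floor so a locally absent label remains
reachable) — then re-estimates μ, σ with fuzzy voxels weighted (1−ε)
toward background and ε toward tumor. Variances are floored at
1e-6·(μ₁−μ₀)² so exactly-two-valued (noiseless plateau) inputs stay
well-posed. Iteration stops when fewer than `tol` (1e-3) of labels change
or after `max_iter` (100). The tumor mask is the hard tumor class plus
fuzzy levels with ε ≥ 0.5; tumor is by convention the higher-mean class.
Constant ROIs raise an error (classes unidentifiable).

*GBM.* Bilateral denoising (3-D brute-force kernel; spatial σ 4 mm, range
σ 0.5 SUV — the range σ is set a few times the noise SD so plateaus smooth
while the lesion edge holds), Richardson-Lucy deconvolution with an
isotropic Gaussian PSF (default 10 iterations; implemented with
spacing-aware Gaussian filters, which is exact for this symmetric PSF),
spacing-aware central-difference gradient magnitude, then watershed.
Basin seeds are the regional minima of the gradient image and flooding
uses **face (6-)connectivity**: central differences leave diagonal gaps in
the gradient shell around a lesion, so 26-connected minima would leak
across the edge and merge the lesion interior with the background into one
basin. Basins are agglomerated on voxel-weighted mean denoised intensity
(closest cluster means merged) until two clusters remain; the tumor is the
cluster containing the hottest ROI voxel, intersected with the ROI and
component-filtered. A single-basin ROI raises an error. The method is
deterministic (skimage's watershed uses a deterministic FIFO flood).

At 4 mm resolution the watershed ridge voxel at a lesion edge genuinely
contains ~50% tumor; its assignment is worth ±1 voxel shell (±30% volume
for a 14 ml sphere), so GBM volumes are alignment-sensitive in a way the
threshold arms are not. This is a property of gradient methods on coarse
grids, not an implementation artifact.

## Contours and DICOM-RT transfer

`mask_to_contours` traces, per axial slice and per in-plane 4-connected
component, the outer boundary (holes dropped — the modeled tumors are
simply connected). Under `voxel_edge` the polygon follows voxel-box edges
(vertices at voxel corners, collinear points merged); under `voxel_center`
it passes through the boundary-voxel centers in boundary order (derived
from the edge loop's owning-pixel sequence). Components with fewer than 3
distinct centers are degenerate under `voxel_center`; they are skipped and
counted. At a pinch corner (two lobes sharing one corner) the tracer takes
the sharpest left turn — an arbitrary but deterministic tie-break.

`contours_to_mask` rasterizes under `center_inside` (voxel center inside
or on the polygon; boundary counts as inside) or `any_overlap` (voxel box
intersects the polygon). Self-touching center-dialect polygons (zero-width
spurs from single-voxel protrusions) are resolved to their valid polygonal
part, which drops the spurs — one concrete mechanism by which a receiving
workstation's reinterpretation of contours shrinks a volume. Consequences,
all tested: `voxel_edge`+`center_inside` on the source grid is the exact
identity; `voxel_center`+`center_inside` can only shrink;
`voxel_edge`+`any_overlap` can only expand; and |Δ| grows with lesion
size (surface-area scaling). RT Structure Sets are written with the
minimal mandatory modules, coordinates as 6-decimal strings (≤5e-7 mm
quantization), no vendor private tags.

## Statistics

Conformity index = intersection/union ("conjunction" read as union — the
only reading for which CI(A,A)=1 and tabulated values below 1 are
possible). ICC is fixed to ICC(2,1) — two-way random effects, absolute
agreement, single rater — computed from the two-way ANOVA mean squares,
with the standard F-based 95% interval (Satterthwaite df); only the lower
limit is reported, matching the conventional presentation of agreement
tables. The Friedman test's post-hoc uses Holm-corrected pairwise Wilcoxon
rather than Scheffé: Scheffé presumes the parametric ANOVA frame, and the
nonparametric ladder is self-consistent. Degenerate cases follow explicit
conventions: identical paired series report p = 1 for both paired tests;
zero differences are dropped from the Wilcoxon statistic; a constant
non-zero paired shift makes the t statistic undefined and raises.

## Pipeline and problem sizes

The default study runs 31 cases and 6 arms; the comparison, resampling
(fine CT grid) and transfer experiments complete together in about a
minute on one CPU. One seed controls the cohort and hence the entire
report; tables are serialized with a fixed float format so identical
configurations yield byte-identical CSVs. Failures in a single case are
logged and the case skipped rather than aborting the cohort.

Test fixture sizes are chosen for precision at small cost: the recovery
fixture is a 15 mm-radius sphere at 8:1 contrast with lesion SUV 5.0 over
background 0.625, which places the absolute 2.5-SUV threshold inside the
partial-volume transition zone (as for a moderately avid tumor) — at high
lesion SUV an absolute 2.5 threshold necessarily over-segments any blurred
boundary, which is the over-segmentation the cohort experiment
demonstrates. Voxel-center rasterization of a sphere tracks the analytic
volume closely for generic centers but can deviate >10% for
lattice-aligned centers (integer-point count fluctuations); tests compare
against a brute-force voxel-count oracle where exactness is asserted.
The resampling-dialect experiment uses noiseless, markedly heterogeneous
small lesions (4–15 ml, texture SD 0.3 × uptake): heterogeneity creates
the peaked profiles for which the five-voxel reference moves under grid
refinement, and omitting noise isolates that mechanism from
interpolation loss at noise spikes.

## Known limitations

- Rigid transforms are inputs; registration estimation is not implemented.
- Oblique (non-axis-aligned) grids are not supported.
- Contour holes and multi-component slices beyond outer boundaries are
  dropped.
- The FLAB and GBM implementations are faithful-in-spirit reconstructions
  of their algorithm families with all constants exposed in configuration;
  no claim of numerical equivalence with any proprietary binary is made.
- Transfer-delta magnitudes on the 4 mm PET grid are ml-scale; clinical
  reports of sub-ml deltas arise from much finer CT-grid contours. Signs
  and size-scaling transfer; magnitudes do not.
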