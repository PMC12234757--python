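# Methods

`cortexrecon` reconstructs continuous 3D cortical maps from sparse,
multi-modal 2D serial brain sections. This note documents the model behind
each stage, the synthetic phantom that serves as the test bed, the
numerical choices, and what the bundled tests do and do not demonstrate
about real data.

## Problem setting

Post-mortem imaging (receptor autoradiography, cell-body and myelin
staining) produces stacks of 2D sections in which each physical slice is
imaged for one *acquisition* (one ligand or stain). Acquisitions interleave
along the cutting axis, sections are lost or excluded, and the tissue is
deformed per slab before sectioning and per section afterwards. Only a
minority of the brain is sampled for any given acquisition (roughly a
quarter to a third of coronal planes in typical receptor data sets), with
heterogeneous 8-bit intensity distributions across acquisitions. The goal
is a per-acquisition 3D volume in the space of a structural reference
volume, plus statistics quantifying alignment and interpolation quality.

Direct intensity-based alignment of such a stack is ill-posed (neighboring
sections come from different modalities), so the pipeline reduces every
alignment problem to a mono-modal one between **gray-matter segmentations**,
and estimates missing intensities **on the cortical manifold** rather than
in the volume, because geodesic distance along the folded sheet — not
Euclidean distance — is the natural metric for laminar data.

## Pipeline

**Stage 1 — rigid inter-section chaining.** Acquisitions are ranked by the
median Michelson contrast `(Imax − Imin)/(Imax + Imin)` of their sections'
tissue pixels. Within each slab, the central section of the
highest-contrast acquisition is fixed; the remaining sections of that
acquisition are aligned outward, each registering to its nearest
already-fixed same-acquisition neighbor toward the center, then becoming
fixed. Lower-contrast acquisitions then register each section to the
nearest fixed section of any higher-contrast acquisition. Registration is
2D rigid, computed on GM masks blurred with a 1 px Gaussian, via
multi-resolution (shrink 4/2/1) Mattes mutual information with a
full-resolution gradient refinement; a correlation-metric raw-intensity
path is available as an option. An optimizer failure, or a fit worse than
the identity, returns the identity with a warning — a damaged section
should degrade gracefully, not abort the run.

Chaining accumulates per-link error as a random walk; on noiseless
phantoms the per-link rotation error is a few tenths of a degree and a
30-section chain stays within ~1° and ~1 px of the true poses modulo the
gauge (the arbitrary pose of the central section). The drift that survives
over longer spans is anatomy-driven (the best shape overlap between
*different* planes is not the true pose) and is exactly what stage 2's
reference volume corrects.

**Stage 2 — multi-resolution alignment to the reference.** Over a strictly
decreasing resolution schedule (default 4, 3, 2, 1, 0.5, 0.25 mm;
3 levels, ending at 1 mm, in the bundled phantom studies), each iteration:

1. transforms every 2D GM mask by its best available chain (stage-1 rigid
   at the coarsest level, plus the accumulated 2D refinements afterwards)
   and assembles a fuzzy 3D GM volume, filling unacquired planes by linear
   interpolation between the two nearest acquired planes (weights inverse
   to axis distance). Fuzzy values are kept — interpolated gap planes are
   inherently fractional; binarization at 0.5 happens only for Dice
   reporting;
2. registers the reference GM slab (cropped to the slab's manually
   identified anterior/posterior bounds when there are several slabs) onto
   the assembled volume: moments-initialized rigid, then affine (both
   correlation metric, dense sampling), then symmetric-forces demons. Each
   stage is kept only if it does not decrease the 0.5-threshold Dice;
3. refines every section in 2D against its corresponding plane of the
   warped reference (nearest plane along the cutting axis, ties toward
   posterior) with demons on lightly blurred masks, again guarded so a
   refinement that lowers the section's Dice is dropped.

All transforms compose lazily: a section's chain maps reconstruction
pixels to section pixels (rigid first, refinements in schedule order), so
any application is a single resampling without accumulation of
interpolation loss. The slab's 3D transform maps reconstruction space to
reference space as `x → A(x + d(x))`; its inverse (needed to carry surface
vertices into slab space) uses the numerically inverted displacement field
(median round-trip residual well under half a voxel in practice).

**Stage 3 — surface-based interpolation.** Depth surfaces
`v_i(d) = (1−d)·wm_i + d·pial_i` span the ribbon at evenly spaced depths
(default 10 surfaces; choose enough that every output voxel between the
borders is intersected). All surfaces are upsampled with one shared
index-level subdivision pattern: per triangle `(A, B, C)`, points
`P = A + αAB + βAC` on the regular barycentric grid with steps of half
the output resolution per edge (`α, β, α+β ∈ [0, 1]`), re-triangulated by
regular subdivision. Using one pattern for every depth surface *and* for
the inflated spheres makes vertex correspondence exact by construction and
guarantees a maximum neighbor distance no larger than the output
resolution on every mesh of the family.

Acquired section pixels are sampled onto each depth surface in slab space
by nearest-neighbor lookup through the full inverse transform chain; a
vertex is sampled when it lies within half a section thickness of an
acquired plane of its acquisition. Because a digitized boundary pixel mixes
GM with WM or background (partial-volume dimming is severe when pixels are
an appreciable fraction of the cortical thickness), sampling snaps to the
nearest pixel of the *eroded* GM mask within a 2 px radius and otherwise
leaves the vertex missing.

Missing vertex values are filled per depth surface by piecewise-linear
interpolation on the unit sphere: the phantom's star-shaped meshes inflate
by exact radial projection (real cortical meshes must supply externally
inflated spheres; the inflation's relative edge-length distortion is
reported); the known vertices are triangulated (convex hull when they span
the sphere, gnomonic-projected Delaunay for localized patches) and each
missing vertex takes the barycentric combination of its containing
triangle. Linear interpolation is used deliberately: estimates are always
bounded by observed values, and it is exact for fields linear in the
ambient coordinates. It will, by the same token, smooth across sharp
areal borders — a known limitation of any interpolant without extra
anatomical information.

Completed fields are projected to the output volume by averaging all
depth-surface vertex values falling inside each cortical voxel; voxels the
sweep misses are filled by iterative neighborhood averaging restricted to
the cortex mask (a Laplacian fill, which reduces to linear interpolation
in 1D gaps).

## The phantom

The synthetic ground truth is a star-shaped folded cortical ribbon: an
ellipsoidal white-matter core (base radius 22 mm, axis scales
(1, 1, 0.82)) whose outer radius is perturbed by an angular fold term
`Re[(u_x + i·u_z)^6]` of 3 mm amplitude, wrapped by a 6 mm GM shell.
Labels and per-acquisition density fields are analytic functions of
position, so sections, vertex samples and volumes all derive from one
closed form. Geometry choices that matter:

* *ellipsoidal base* — every coronal cross-section is elliptical, so
  in-plane rotation is observable everywhere (a circularly symmetric
  section makes rotation recovery meaningless);
* *even fold order* — cross-sections are mirror-symmetric, so the best
  shape overlap between neighboring planes carries no systematic in-plane
  drift and chaining accuracy can be assessed against ground truth;
* *star-shapedness* — sphere inflation is exact radial projection,
  isolating interpolation correctness from inflation quality (production
  grade inflation is out of scope; real meshes bring their own spheres).

Density fields are band-limited random functions of direction
(modes `(d_j·u)^k`, `k ∈ {1..3}`, weights `exp(−k·s)` with smoothness
`s = 1`), normalized by their realized amplitude over a dense direction
sample so the field actually spans its declared range; as `s → ∞` the
field degenerates to a constant. Intensities follow
`value = gain·density + offset + N(0, 4)` clipped to [1, 255], with
per-acquisition gains spanning most of the 8-bit range (GM ≈ 100–250,
WM ≈ 25–45), emulating the strong heterogeneity of multi-modal sections.
An optional polarity flip emulates inverted stains.

Sections are cut at 0.25 mm pitch from a (64, 256, 64) truth grid with
1 mm in-plane pixels — sections much thinner than the reference grid, as
in real serial sectioning — while the reference volume is the 64³ 1 mm
block-mean binarization of the truth GM. The default sampling scheme keeps
30% of tissue-bearing planes, cycles 4 acquisitions, splits the stack into
2 slabs separated by 3 lost planes, and perturbs each kept section by a
rigid jitter (≤5°, ≤3 px), a ≤1 px smooth warp, and a per-slab 3D affine
jitter (≤2°, ≤2 mm) applied to the truth before slicing (keeping the
ground truth invertible). Each section is rendered analytically at the
inverse-mapped coordinates with 3×3 subpixel area-averaging — the
integration a digitizing camera performs — so section edges are
anti-aliased without any resampling step whose artifacts would contaminate
ground-truth recoverability.

**What the phantom does not emulate:** real histological texture, tears
and folds, staining artifacts, non-specific binding, laminar intensity
profiles (fields vary only tangentially), slab-boundary tissue loss beyond
whole missing planes, and true (non-affine, non-invertible) fresh-tissue
deformation. Passing the phantom studies therefore demonstrates the
correctness of the machinery under a known forward model, not performance
on real autoradiographs.

## Segmentation

The segmenter interface is a plug-in (`predict(Image2D) → GMMask`). The
intended production segmenter is a U-Net trained on synthetic images
rendered from any labeled volume by the bundled generator: one random
affine per group of 500 sections (per-axis scale ~ U(0.9, 1.1), rotations
~ U(0°, 15°)), the cortex split into k ~ U{0..11} layers of
Dirichlet(1,…,1)-proportional thickness, a random Gaussian-drawn intensity
per class, a skull ring in 50% of examples, and
smoothing/noise/scale/crop augmentations; paired targets are the
{background, cortex, WM} labels plus a boundary-pixel channel (loss
weighting of the boundary task is left to the external trainer). Network
training itself is out of scope; the default working segmenter is
classical: Otsu thresholding over a 256-bin histogram of the tissue
(nonzero) pixels, polarity chosen automatically by a ribbon-likeness score
(fraction of mask in the largest connected component times one minus its
solidity — a cortical ribbon is a dominant, low-solidity component),
followed by largest-component cleanup. When a primary segmenter returns an
empty mask the Otsu fallback is used and logged; if both are empty the
section is excluded and the run continues.

The class-intensity distributions and augmentation strengths have no
canonical values; they are recipe configuration with documented defaults.

## Quality control

Sections are excluded automatically when (a) their GM area is below half
the slab's median area (tissue fragments, typically slab-end sections),
or (b) below 75% of the median area of their 4 nearest acquired neighbors
(locally missing cortex), plus an always-available manual exclusion list.
Rule (b) automates the "missing more than 25% of the cortex" criterion;
rule (a) automates the exclusion of fragment sections. Exclusion reasons
are recorded on the section records and in the log.

## Validation statistics

* **Windowed Dice**: mean of plain Dice scores over a dense 5×5 sliding
  window, skipping windows whose prediction window is tissue-free, so
  contiguous missing tissue in an otherwise aligned section barely
  penalizes the score (windows straddling the damage edge still lose a
  little — an exact score of 1 under damage is not achievable with
  windowed plain Dice).
* **Inter-section Dice**: per section, the mean Dice with its nearest
  acquired anterior and posterior neighbors (single-sided at slab ends);
  measures reconstruction smoothness. At phantom scale this statistic has
  an anatomy ceiling well below 1 (neighboring acquired planes are up to
  several mm apart), which is why section pitch is much finer than the
  reference grid and fragment sections are excluded.
* **Patch validation**: seeds are drawn among vertices intersecting
  acquired sections; hop rings 0..n (n ~ U{2..6}) grow within the seed's
  section plane; rings 0..n−1 are masked out and re-estimated from ring n;
  the mean over the core patch (rings 0..m, m ~ U{1..5}, m < n) is
  compared with the truth, with seeds rejected unless all estimation
  distances fall in 0.05–1.2 mm. Rings use graph hops; the physical window
  reconciles hop counts with millimetres.
* **ROI accuracy**: SLIC superpixels (~21 mm² mean area) on raw sections;
  accuracy `1 − |true − est|/true` of ROI means after applying the 2D
  chain, and after reading the continuous 3D reconstruction under the
  transformed parcellation; ROIs with zero true mean are excluded.
* **SUVR + permutation test**: PET-style volumes are normalized by the
  mean WM activity; within- vs between-group correlation lists are
  compared by the absolute difference of means under label permutation,
  with add-one smoothing `(1 + #{perm ≥ obs})/(n_perm + 1)`. Under a
  simulated null the p-values are uniform (KS-checked); the statistic is
  monotone in effect size.

## Numerical choices and degenerate inputs

* Indices are 0-based, pixel-center; world units mm; the cutting axis maps
  to array axis 1. Background is 0 everywhere; tissue strictly positive.
* `dice(∅, ∅) = 1` (two empty masks agree perfectly), so windowed Dice
  never produces NaN on tissue-free windows.
* Volume resampling uses exact block averaging for integer factors
  (alias-free, mean-preserving) and tri-linear sampling at edge-aligned
  centers otherwise, clamped at the physical boundary.
* Rasterization of the ribbon marks voxels containing depth-sweep samples,
  with the sweep inset half a voxel from each border so the voxelized
  volume is unbiased.
* Registration metrics use dense sampling — every run is deterministic for
  fixed inputs; all randomness in the package flows from explicit seeds.
* Degenerate inputs fail loudly and early: constant images cannot be
  thresholded, empty masks cannot be ranked, increasing resolution
  schedules are rejected at config validation, empty reference planes
  yield flagged identity refinements rather than spurious warps.
* Stage outputs are cached on disk keyed by a hash of the configuration
  (seed, schedule, QC policy, inputs), so a re-run recomputes only stages
  whose caches were removed.

## Problem sizes

The bundled end-to-end studies use the 64³ 1 mm reference phantom with a
4 → 2 → 1 mm schedule (about 60 sections), the scale at which the full
reconstruction, its determinism re-run and the component harnesses all
complete in a few minutes on one CPU. The machinery is scale-free: the
schedule, depth-surface count and mesh subdivision are configuration.

## Known limitations

* The 2D refinements are carried across resolutions as a composed list of
  displacement fields rather than re-diffeomorphized; extreme warps could
  in principle fold (guarded only by the per-section Dice check).
* Linear surface interpolation smooths sharp receptor-architectonic
  borders by design.
* Sphere inflation in-package is radial projection, valid only for
  star-shaped meshes; real cortical surfaces must bring externally
  computed spheres.
* Subcortical structures are outside the cortex mask and are not
  reconstructed.
* The intensity model knows nothing about film calibration: outputs are in
  acquisition-native gray values, not receptor densities.
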