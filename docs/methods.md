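# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `tissuescope3d`. It is written for users who need to judge
what the package computes and what its validation does — and does not —
demonstrate.

## Imaging model and de-noising (BFBD)

Confocal stacks are photon-limited: recorded intensity relates to photon
count as `I = α·N + β`, where `α` (a.u./photon) is the detector conversion
gain and `β` the digitization offset. The noise variance at intensity `I` is
therefore `V(I) = α·(I − β)`. Deep in scattering tissue the acquisition gain
is raised, so `α` grows with depth; the model stores one `α` per calibration
slab (default 16 planes) and interpolates linearly in z, clamping beyond the
end slabs.

Calibration bins the half squared difference of sequential z-planes (a local
variance estimate, unbiased when the underlying signal varies slowly along z)
by the pair-mean intensity (32 equal-width bins, bins with < 50 voxels
dropped) and fits the line `V = α(I − β)` with an outlier-tolerant
(iteratively re-weighted, Cauchy-loss) estimator; `β` is the median over
slabs, after which `α` is re-fitted per slab through `(β, 0)`. The
calibration needs intensity diversity in the field of view; a constant image
raises a flagged `CalibrationError`.

BFBD de-noising exploits the axial elongation of the confocal PSF: per x–y
pixel, the background varies smoothly along z and is estimated by the same
outlier-tolerant line over a 5-plane sliding window (foreground structures
are sparse *positive* outliers along z, which the Cauchy loss discounts).
Residuals above `1.25·σ` (σ from the noise model at the local intensity and
depth) are kept as foreground; background and foreground are independently
smoothed with a σ = 0.5 voxel Gaussian and summed. Defaults (window 5,
threshold 1.25 in noise-sigma units) are the operating point used throughout.

## Mosaics and rigid registration

Tile grids (~10 % nominal overlap) are aligned by maximizing the global
metric `G`, the sum of normalized cross-correlations of all neighbour
overlaps. `G` is maximized by block-coordinate ascent: pairwise NCC maps are
precomputed on a ±6 voxel cube around the nominal offsets, then each tile in
turn moves to the position in its whole admissible cube that maximizes its
summed correlation to its neighbours, until no move improves `G`. Single-step
(±1 voxel) moves were found to stall in joint local optima when several tiles
are misplaced at once; whole-cube moves converge in 2–3 sweeps. The first
tile anchors the gauge.

Fusion uses multi-band blending (4 Laplacian bands): low-frequency content
blends over wide regions and high-frequency content over narrow ones, which
removes seams without ghosting; voxels covered by exactly one tile are
copied exactly.

High-resolution stacks register rigidly (z-rotation + translation) into the
low-resolution reconstruction on a three-level pyramid (×0.25, ×0.5, ×1).
The coarsest level does an exhaustive rotation search in ±15° (3° steps) —
the convergence basin required by the subsequent refinement — then each
level alternates translation-by-NCC-peak with rotation refinement from the
angular cross-correlation of polar-transformed mean projections, 3
iterations per level. Sections are mounted flat, so only z-rotation is
modelled; full 3D rotation is out of scope.

## Section surfaces, unbending, and vessel segmentation

The measured surfaces `ym1`, `ym2` are the first/last z above the global
Kapur threshold per x–y column (after σ = 1 voxel smoothing along z); empty
columns are inpainted from the nearest valid column. Refinement minimizes a
negative log posterior with three parts per column: Cauchy data terms
(scale `s`) tying each refined surface to its measurement — heavy-tailed, so
vessel-induced dips act as discountable outliers; a Gaussian (scale `σ`)
tying the local thickness `y2 − y1` to the typical thickness `t0` (median of
the measured thickness field); and Laplace smoothness (rate `λ`) over the
8-neighbourhood of **both** surfaces. Parameters come from the measured
surfaces: `t_MAD` is the median absolute deviation of the thickness
(floored at 1 voxel, flagged), `s = σ = (π/2)·t_MAD`, and `λ` is the Laplace
maximum-likelihood estimate `1/mean|Δy|` on neighbour height differences.

Two deliberate modelling choices: (i) the thickness Gaussian is centred on
`t0` — an uncentred coupling would collapse the surfaces under minimization,
and only the centred form makes the measured flat configuration the
maximum of every factor; (ii) smoothness applies to both surfaces — with a
one-sided prior, the optimizer relieves the thickness coupling at vessel
dips by dragging the unregularized surface instead of lifting the dipped
one (measured on bent-slab phantoms).

Minimization is iterated conditional modes: integer height candidates within
±3·t_MAD per column, updated on a 2×2 four-colouring (no two columns of a
colour are 8-neighbours, so quarter-sweeps vectorize while remaining true
coordinate-wise updates); moves are accepted only when they lower the
conditional energy by > 1e-9, which makes the energy non-increasing and the
sweep count finite. Unbending fits a quadratic B-spline to each refined
surface and linearly re-samples each column so both surfaces become planes
(target thickness = median thickness); the inverse remap is available for
round-trip checks.

### Local maximum-entropy (LME) thresholds

The Kapur criterion (maximize the sum of background and foreground Shannon
entropies; ties break to the lowest bin) is computed per overlapping cube
(default 32 voxels/side, 50 % overlap, 128 bins over the cube's own range)
and tri-linearly interpolated per voxel.

Two failure modes of the plain criterion on realistic fluorescence
histograms had to be addressed. On a histogram composed of a narrow
background mode, a PSF-halo continuum and a log-normal staining tail, the
single entropy split lands deep inside the tail (sensitivity ~0.1–0.2 even
at 10:1 SNR; Yen's entropic criterion fails identically, so this is the
criterion, not the implementation). The cube threshold is therefore the
*iterated Kapur descent*: Kapur is re-applied to the below-threshold class
while the next split stays above the local background band
(the below-class median + 6 robust SD), and the result is clamped to that
band. Secondly, a cube containing no structures splits inside background
noise; a cube is valid only when its foreground fraction lies in
[0.2 %, 50 %] *and* the threshold clears the cube's majority-class band
(median + 4 robust SD). Invalid cubes inherit the nearest valid cube's
threshold; if no cube is valid, a global threshold with a permissive
foreground cap is tried, and failing that the image is treated as
structure-free. Dark structures inside bright tissue (vessel lumina) are
the mirrored problem: `lme_threshold_field(mirror=True)` runs the same
descent on negated intensities and maps the threshold back — the vessel
path uses this. Large unstained vessels are then segmented as
below-threshold components between the refined surfaces, size-filtered at
500 µm³.

Inter-section vessel gaps are bridged by blending "smoothed indicators" of
the facing cross-sections — logistics of the signed distance to the mask
boundary — linearly across the gap and thresholding at 0.5; signed-distance
blending makes the interpolated cross-section track an offset between the
faces linearly, which a hard 0/1 indicator blend does not. Faces whose
dilations do not overlap are left unbridged with a warning.

## Meshing, gradient tuning, skeletons

Masks are meshed per connected component with marching cubes (padded, so
meshes are watertight; border-touching components are capped and flagged);
winding is normalized so vertex normals point outward. Rasterization back to
voxels uses exact scanline parity counting (ray–triangle crossings per
column with a sub-voxel jitter so rays never hit edges), and is the inverse
of meshing on clean masks.

Thresholded masks overestimate thin-structure diameters (PSF + closing).
Tuning moves each vertex along its normal to the intensity-gradient maximum
within a search range (±0.3–0.5 µm defaults), with parabolic sub-sample
refinement, Laplacian smoothing of the displacement field, and 2 passes. The
default target is the maximum of −dI/dt (the edge falling away from the
object interior): with the unsigned |dI/dt|, the two walls of a thin shell
can both snap to the same strongest edge and collapse the shell. For a
blurred step the gradient extremum sits exactly on the step, so tuned radii
are accurate to ≲ 0.25 voxel for structures larger than the PSF. For
structures *thinner* than the PSF (the 0.5 µm sinusoid wall), gradient
extrema sit a blur-width away from the true faces — no gradient criterion
can sharpen such a wall, which is why the sinusoid reconstruction keeps the
LME mask as its voxel output and uses tuning only for the outer-radius
measurement (filled tube, magnitude mode; the surface snaps to the wall
ridge flank).

Active-mesh expansion (cells, nucleus regrowth) is an explicit balloon:
each free vertex moves `0.2·pressure` voxels along its outward normal plus a
*tangential* Laplacian regularization (the umbrella operator's normal
component would deflate the balloon against the pressure). A vertex freezes
when it crosses an intensity ridge (value ≥ an Otsu floor and no longer
rising ahead, evaluated on a σ = 1.5 voxel smoothed copy so noise cannot
freeze it), when the voxel ahead is a barrier, or when another label claims
it in a shared occupancy grid. Defaults: pressure 1.0, rigidity 0.4, stop
when the maximum motion stays below 0.01 voxel for 10 iterations.

Skeletonization thins the mask to a medial axis (scikit-image), builds a
graph whose nodes are endpoints/junctions and whose edges carry the
centreline polyline, length and mean radius (Euclidean distance transform
sampled along the centreline), prunes leaf edges shorter than twice the
local radius, and contracts pass-through nodes. Branch angles are measured
between arm tangents averaged over the first 5 µm from the junction.

## Nuclei: support, splitting, DNA content

Nucleus support comes from the LoG scale-space maximum projection (LoGMP)
over σ = r/√2 for the expected radius range (3.5–5.5 µm), thresholded at
15 % of its maximum. A band-pass blob detector integrates over whole nuclei,
so uneven intra-nuclear staining and noise barely move the support — an
intensity threshold loses the dim halves of nuclei at 2:1 SNR. Support
components are meshed and gradient-tuned, then each object is fitted by a
single minimum-volume enclosing ellipsoid (Khachiyan's algorithm on the
convex-hull vertices, tolerance 1e-3) and by two MVEs (split by the plane
through the centroid normal to the principal axis, two rounds of
nearest-ellipsoid reassignment). The misfit is
`MSE = Σ((p−c)ᵀE(p−c) − 1)² / (n − 9)` (9 = ellipsoid parameter count; for
the double model each vertex scores against its nearer ellipsoid). The
`ln MSE` of the better model across all objects is fitted by a two-Gaussian
mixture; the threshold is the upper 95 % limit (μ + 1.96σ) of the
lower-mean component — objects below keep their best-model label
(mono/double), objects above are multi-nuclear. A degenerate mixture falls
back to a single Gaussian + 95 % quantile, flagged.

Doubles split along their two-ellipsoid model (each voxel to the nearer
ellipsoid) unless the LoGMP inside the object shows ≥ 3 blobs, in which case
the object is treated as multi-nuclear: LoGMP seeds (local maxima above 10 %
of the in-object maximum) grow by active-mesh expansion constrained to the
parent object, and leftover parent voxels go to the nearest seed. All
splitting work happens in the object's bounding box. On the 150-nucleus
synthetic field (radii 5–7 µm; singles, doubles, triples at overlap factors
0.55–0.95 of the radius sum; 10 % background; σ = 1 Gaussian blur; 5 %
salt-and-pepper noise) split-decision accuracy is 89–93 % across seeds; the
residual errors are deep-overlap triples whose middle LoG maximum vanishes
and occasional over-seeding by salt noise.

DNA content is the integral DAPI intensity over voxel centres inside the
nucleus mesh. Between samples, histograms are aligned by the stretch factor
minimizing the least-squares projection residual
`d(s) = Σf₀² − (Σ f₀·f_j(s·x))² / Σ f_j(s·x)²` (grid search on [0.5, 2] +
bounded refinement).

## Cell segmentation

Cells expand from the nucleus meshes on the (de-noised) cortex channel, all
cells concurrently in 60-iteration rounds sharing the occupancy grid — with
sequential full expansion, the first cells overrun dim walls before their
neighbours exist. After expansion the meshes are rasterized; contested
voxels go to the nearest nucleus, and unclaimed tissue within 1.5 µm of any
cell (the cortex band itself, since fronts stop at the wall ridge) is
assigned to the nearest cell, making the cells a strict partition. Adjacent
cells merge into one bi-nucleated cell when their nucleus distance is below
12 µm *and* no cortex wall crosses the bundle of probe lines along the
nucleus–nucleus axis (median of per-line maxima below the midpoint between
the background and cell-boundary medians — the midpoint form keeps the rule
meaningful when a dim cortex approaches the background). Cells whose nuclei
lie within a margin of the image border are flagged `boundary` and excluded
from statistics.

## Synthetic benchmark

The generator emulates the four stained structures of liver tissue at high
resolution: BC as solid tubes (r = 0.5 µm), sinusoids as hollow tubes
(2.5/3.0 µm inner/outer), nuclei as spheres (r = 3.5–5.5 µm; 20 % of
placements are touching doubles and 5 % triples, centre distance 0.75–0.95
of the radius sum), and cell borders (0.5 µm) of the nearest-nucleus
partition bounded by the sinusoids. Tubular centrelines grow as branching
random walks (branch arms at ±55° from the parent, i.e. ~110° inter-arm;
8° per-step direction noise). Default densities are adult-liver
morphometry: 2.9·10⁻³ µm/µm³ length density for both networks and
1.6·10⁻⁴ nuclei/µm³ (≈ 6 250 µm³ per cell). The ground-truth outlines are
parametric rather than extracted from real images — the one substantive
departure from the benchmark this package emulates — so reconstruction
scores agree statistically, not per-voxel.

Degradation is order-fixed and per-stage bypassable:

1. **Uneven staining** — one log-normal draw (arithmetic mean 1000 a.u.,
   log-sd 0.5) per 6³ block, refined per voxel (log-normal around the block
   value, log-sd 0.2), masked by the structure; the "sd 0.5 / 0.2" values
   are read as log-space sd (an absolute sd of 0.5 a.u. on a mean-1000
   variable would be negligible and visibly wrong). Uniform background =
   foreground mean / SNR, for SNR ∈ {10, 4, 2}.
2. **Confocal PSF** — separable kernel; lateral Gaussian σ = 0.21·λ/NA,
   axial Gaussian–Lorentzian blend (30 % Lorentzian weight) with
   σ = 0.66·λ·n/NA², NA = 1.3, n = 1.49 (cleared tissue); unit sum.
   Excitation wavelengths: 568 (BC), 647 (sinusoids), 780 (nuclei),
   488 nm (cell borders).
3. **Depth-dependent Poisson noise** — `I = α(z)·Poisson(I/α(z)) + β` with
   α linear from 1.0 to 3.0 a.u./photon over the stack and β = 100 a.u.

Everything is bit-reproducible per seed.

### What the benchmark shows — and what it cannot

Measured with the full pipeline (de-noise → LME → meshes/splitting/cells):
nuclei voxel F ≈ 0.87–0.90 per SNR; BC F ≈ 0.66–0.79 (average ≈ 0.74);
BC tuned radius ≈ 0.58–0.64 µm (true 0.5; the positive bias is the expected
gradient-extremum offset for sub-resolution tubes; the radius is the
median vertex-to-skeleton distance, robust to tube end-caps); sinusoid outer radius
≈ 2.9–3.1 µm (true 3.0). Two quantities fall short of what reconstruction
of *this* class of images could ideally give:

* **Sinusoid wall voxel F (~0.58 average).** Under the staining model above,
  the globally optimal threshold on noiseless stained+blurred walls caps F
  at 0.81 (10:1) to 0.69 (2:1) — the dim-stained patches of a sub-resolution
  wall are genuinely indistinguishable from background, and gradient tuning
  cannot sharpen a sheet thinner than the PSF. Voxel-accurate wall scores
  materially above that ceiling would require priors (known wall thickness)
  that the pipeline deliberately does not use.
* **Cell F (~0.83) and volume error (~8–18 %).** Cell scenes run at 0.6 µm
  sampling (112³ voxels ≈ a 67 µm block): interior, non-boundary cells only
  exist when the block spans ≥ 3 cell diameters, which at full 0.3 µm
  sampling would need ≥ 256³ voxels and ~20 min per scene. The coarser
  sampling alone costs ~0.05–0.08 F in boundary quantization on 11-µm-radius
  cells, and low-SNR nucleus-detection errors distort individual partitions.

Because the generator's ground truth is parametric, passing scores show the
pipeline recovers *structures with these geometric and photometric
statistics*; they do not certify performance on real tissue, where staining
correlations, anisotropic deformation and optical aberrations are richer.

## Cell classification

Each nucleus yields 74 parameters: MVE geometry (volume, area, sorted
axis ratios, sphericity `π^{1/3}(6V)^{2/3}/A`, radius mean/variance,
area-weighted shape index and curvature variation measure on a
Taubin-smoothed copy of the mesh — raw marching-cubes surfaces are voxel
staircases whose per-vertex curvature is meaningless); DAPI and Flk1
mean/sd/skewness/kurtosis inside the nucleus; 13 Haralick features of the
normalized grey-level co-occurrence matrix averaged over 65 matrices (13
unique 3D directions × distances 1–5, 256 levels, symmetric); differential
box-counting and Minkowski–Bouligand (blanket) fractal dimensions of the
intensity landscape (box sizes/radii 1–5); gliding-box lacunarity
Λ(b) = ⟨m²⟩/⟨m⟩² for b = 1–5 over boxes fully inside the nucleus, with
normalized (Λ_b/Λ_1) and log variants; the area-weighted mean DAPI gradient
at triangle centres; and mean phalloidin/Flk1 intensity in 11 one-voxel
shells (0–10) around the mesh, taken as per-shell rings (not cumulative).
Channels are histogram-equalized (256 levels, whole stack) first.

The LDA cascade runs three binary discriminants in order — hepatocyte vs
rest, SEC vs rest, Kupffer vs stellate — on the top-k features by Fisher
score `F_i = Σ_k n_k(μ_ki − μ_i)² / Σ_k n_k σ_ki²`; k is chosen by
leave-one-out accuracy over the Fisher-ranked prefix. The Bayesian-network
classifier discretizes every feature into 5 equal-population bins (ties
never split), orders features by add-one-smoothed mutual information with
the class, learns the structure with the K2 algorithm (Cooper–Herskovits
score, greedy parent addition, ≤ 3 parents, class node first) and predicts
by maximum posterior with add-one-smoothed CPTs. Both are exercised on
synthetic data; the published training set of real nuclei is not available,
so real-tissue accuracies are out of scope here.

## Morphometrics and zonation

Network statistics normalize totals by tissue volume (volume fraction,
length density mm/mm³, length-weighted mean radius, branch-angle
distribution, node cardinality and density). The cylinder-consistency check
compares the measured volume fraction against `V_c = π·r_s²·L_s`; on ideal
generated cylinders the ratio is 1 within discretization error. The lobule
coordinate is `χ = 50·((|D − d_pv| − |D − d_cv|)/D + 1)` with d's the
Euclidean distances to the nearest central/portal vein surface and
`D = d_cv + d_pv` along the realized geometry; χ is clamped to [0, 100]
(0 at the CV surface, 100 at PV). Zonation profiles are relative densities:
the population share per χ bin divided by the population's overall share,
so a uniformly distributed population is flat at 1; empty bins are missing,
not zero. Ploidy clustering runs Ward-linkage agglomerative clustering on
standardized (volume, DAPI integral), separately for mono- (k = 4:
2n/4n/8n/16n) and bi-nucleated (k = 3: 2×2n/2×4n/2×8n) cells, labels
ordered by ascending DAPI. Cell-size and DNA-content distributions are
fitted by log-normal mixtures (EM in log space, k-means++ init, fixed
seed).

## Problem sizes used for validation

The test suite and the acceptance script run the benchmark at reduced
sizes chosen for a single CPU: tubular/nuclei scenes at 96³ voxels
(0.3 µm), cell scenes at 112³ voxels (0.6 µm), the splitting field at 128³
(1 µm), with three scene seeds per SNR in the acceptance script and one in
the test suite. Scores at these sizes carry wider sampling error than the
full-size protocol (three 256³ scenes per SNR), particularly the
cell-volume statistics, which rest on ~10–15 interior cells.

## Known limitations

* Sub-resolution walls are reconstructed at the fidelity thresholding
  permits (see above); wall-thickness priors are deliberately not used.
* Skeleton-based radii on voxel masks carry ±½-voxel discretization;
  mesh-based radii inherit the gradient-extremum bias for thin tubes.
* The ICM surface model assumes one contiguous tissue slab per column;
  sections with complete through-holes violate the thickness coupling.
* The benchmark does not emulate lobule-scale vessel geometry (PV/CV
  placement), staining correlations between channels, or mechanical
  deformation; the mosaic and surface modules are validated on their own
  phantoms instead.
* Cell classification is validated on separable synthetic classes and
  recovery properties, not on real annotated nuclei.
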