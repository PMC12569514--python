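# Methods

`metalspot` integrates two spatially resolved modalities measured on serial
sections of the same tissue block: per-isotope elemental intensity maps from
laser-ablation ICP mass spectrometry (µm-scale pixels) and Visium-style spot
transcriptomics (55 µm capture spots at ~100 µm pitch). The workflow cleans
the elemental maps, registers them into the slide's µm frame, aggregates
pixels onto spots, converts abundances into local hotspot statistics, and
relates those statistics to tissue architecture, cell-type composition, and
gene expression. Because no patient data accompany the workflow, every stage
is validated against a synthetic generator that plants known structure.

## Elemental-map cleanup

**Tissue detection.** Tissue is segmented on the channel-sum image:
Gaussian smoothing (`sigma_px`, default 2 px) damps single-pixel outliers,
a quantile threshold separates background from tissue, and binary opening
then closing (disk radii 2 px) remove speckle and close holes; connected
components under `min_area_px` (64 px) are discarded. The threshold
quantile should approximate the background fraction of the frame — the
bimodal intensity histogram puts any such quantile into the gap between the
background and tissue modes. The function default is 0.5 (tissue ≈ half the
frame); the pipeline default is 0.35 because the synthetic tissue ellipse
covers ~64% of the grid. Detection is idempotent: re-running it on the
masked image reproduces the mask.

**Stripe removal.** Ablation rasters leave directional intensity stripes
along the scan axis. The channel-sum is smoothed by Perona–Malik
anisotropic diffusion (10 iterations, conduction scale κ = 0.5 on the
std-normalized image, dt = 0.2), which flattens texture while keeping the
stripe edges sharp. The gradient magnitude is thresholded at its 0.98
quantile and passed to a probabilistic Hough transform restricted to within
±5° of the raster axes — ablation stripes are directional, and the angular
gate prevents genuine oblique tissue boundaries from being treated as
artifacts. Two further choices matter in practice:

- the mask is eroded by 3 px before edge thresholding, because the tissue
  outline is itself the strongest gradient in the image and would otherwise
  both dominate the quantile and seed spurious lines;
- accepted segments are extrapolated along their own direction to the grid
  borders, since a raster stripe physically spans the whole ablation line
  while the Hough segment stops wherever edge support thins.

Detected lines, dilated to a ±2 px band, form the stripe mask. Stripe
pixels are replaced per channel by the median of non-stripe pixels in a
window perpendicular to the stripe (nominal 7 px, doubled until clean
pixels are reached); median in-fill is robust to residual outliers where
interpolation is not. Pixels outside the stripe mask are returned exactly
unchanged, and a stripe-free map passes through bit-identical.

**Edge erosion.** Labile metals (notably iron) wash out at tissue margins.
The analysis mask is eroded inward by `depth_px` (pipeline default 3 px ≈
15 µm) using the 4-connected cross element iterated, i.e. an L1 ball.

**Pseudo-log.** Abundances are transformed with log1p: monotone, defined
at zero, and strongly damping for the single hot pixels that particulates
and spectral interferences produce.

## Co-registration and aggregation

A 3×3 planar homography maps map pixels (x = col, y = row, origin top-left)
to the whole-slide µm frame. It is estimated from ≥ 4 manually picked
fiducial pairs (30 in the emulated protocol) by the normalized direct
linear transform, then refined by Levenberg–Marquardt on the reprojection
residuals; the reported RMSE is in target µm. Under 1 µm isotropic noise on
30 landmarks, reprojection RMSE stays below 2 µm.

Each in-mask pixel centre is transformed to the µm frame and assigned to
its nearest spot centre if and only if the distance is within the capture
radius (spot diameter / 2 = 27.5 µm by default — the capture-spot radius,
not half the pitch, so inter-spot pixels stay unassigned). The spot value
per element is the mean of the assigned pixels' log1p intensities; the
transform precedes averaging so a hot pixel cannot dominate its spot. Spots
with fewer than `min_pixels` (5) assigned pixels are dropped — these are
rim spots clipped by mask erosion. Assignment to the nearest centre makes
the pixel→spot map a partition: no pixel is counted twice.

## Hotspot statistics

The Getis–Ord Gi* statistic scores each spot's neighbourhood sum against
its expectation under spatial randomness:

    z_i = (Σ_j w_ij x_j − x̄ W_i) / (S √[(n Σ_j w_ij² − W_i²)/(n−1)])

with binary distance-band weights (w_ij = 1 within 100 µm, self included —
the centre-to-centre pitch of adjacent spots), W_i the neighbour count, and
x̄, S the global mean and *population* (n-denominator) standard deviation,
per the canonical Gi* derivation. Positive z marks a hotspot, negative a
coldspot; p-values are two-sided because both directions are of interest.
Degenerate cases (constant field, neighbourhood spanning all spots) return
z = 0, p = 1. z is invariant to adding a constant or scaling by k > 0.

Conditional permutation inference holds the focal value fixed and permutes
the remaining values over the other spots; since a permutation leaves the
global mean and SD unchanged, only the local sum is resampled, and
p = (1 + #{|z_perm| ≥ |z_obs|}) / (1 + n_perm). One bank of index
permutations is shared across spots (the standard conditional-randomization
device), making the whole computation deterministic given a seed.

No multiple-testing adjustment is applied at the spot level: the z-scores
are used downstream as a spatially smoothed abundance feature, not as a
per-spot discovery list. On smooth fields z tracks the raw spot values
closely (Spearman ≥ 0.9 on the synthetic lattice); on the default synthetic
run the average concordance is ~0.82 because elements without planted
region structure are Gaussian-random-field noise at a 50 µm length scale,
rougher at the 100 µm neighbourhood scale than real tissue fields.

## Architecture and cell-type association

Per element, Gi* z is regressed on the architecture label (one-way OLS,
cell-means coding). The estimated marginal means equal the arithmetic group
means in this design; their standard errors use the pooled residual
variance. All pairwise contrasts are reported with Tukey-adjusted p-values
(studentized-range distribution at q = |t|√2, k groups, residual df) —
Tukey is the standard all-pairs adjustment in the EMM workflow. Contrasts
are exactly antisymmetric. A z-scored EMM matrix is emitted for heatmap
display only; statistics are computed on unscaled values.

Sparse pathologist annotations are completed by iterative k-NN majority
vote (k = 4) over the spot lattice; ties break lexicographically by label
name, the unassigned count is non-increasing per pass, and unreachable
spots keep the label "unassigned" with a warning.

Cell-type proportions (an upstream deconvolution input) are related to
element Gi* z by Spearman correlation per (cell type, element) pair;
constant columns yield a missing ρ with p = 1. The matrix is ordered for
display by average-linkage Euclidean hierarchical clustering of rows and
columns with scipy's deterministic leaf order.

## Metal–gene screen and enrichment

Counts are normalized to 10 000 per spot and log1p-transformed; zero-count
spots are excluded. Every gene is Spearman-correlated (average ranks for
ties; two-sided t-approximation p, matching `scipy.stats.spearmanr`)
against one element's Gi* z vector. The family size G is the number of
genes submitted; significance requires p_raw < 0.05/G (Bonferroni), and
p_bonf = min(1, G·p_raw) is reported alongside. Per element, three ranked
lists of at most 150 genes are extracted — positive ρ, negative ρ, and by
magnitude — ordered by adjusted p with ties broken toward larger |ρ|, then
gene name; only Bonferroni-significant genes are eligible, so lists may be
shorter than 150.

Over-representation of a gene list in a GMT collection uses the
hypergeometric upper tail P(X ≥ k) with the universe fixed to the genes
actually tested in the screen — using all annotated genes instead would
inflate enrichment beyond the screen's multiple-testing family. Enrichment
is one-sided (depletion is not reported), and Benjamini–Hochberg adjustment
is applied within each collection separately; no correction is applied
across elements.

## Synthetic data: what it emulates and what it does not

The generator emulates the acquisition geometry — 5 µm elemental pixels,
55 µm spots on a square 100 µm-pitch lattice clipped to an elliptical
tissue, a known pixel→µm homography with 30 sampled fiducials — and plants:

- four architecture regions (tumor, interface, muscularis, serosa) as a
  Voronoi partition whose seeds are deliberately asymmetric so region
  boundaries run oblique to the raster axes and cannot be mistaken for
  stripes;
- per-element fields = region mean + Gaussian random field (white noise
  convolved with an isotropic Gaussian, length scale 10 px = 50 µm,
  SD 0.5) + radially decaying hotspot blobs; the default scenario enriches
  Cu in the tumor (mean 6 vs 3) and adds one Cu blob;
- artifacts applied only to the "as-acquired" copy: multiplicative row
  attenuations at configured rows (0.5 and 0.4 by default) and a 3 px
  edge-washout band attenuated by 0.5;
- negative-binomial counts (variance µ + 0.5 µ²) with log-normal baseline
  means; for coupled genes the log-mean adds slope × standardized
  spot-level element value, the slope calibrated per gene by seeded
  Monte-Carlo bisection so the counts reach a target Spearman ρ (0.5 by
  default, 10 genes per element) against the clean element field —
  coupling acts on the pre-artifact field so the planted ρ is well defined
  and artifact robustness is measurable;
- Dirichlet cell-type proportions with region-specific concentration
  vectors, one cell type (Macrophage) modulated by the Cu field.

A square lattice replaces Visium's hexagonal packing: the Gi* neighbour
logic depends only on centre distances, and 100 µm pitch preserves the
"adjacent spots ≈ 100 µm" structure. Defaults (400×400 px ≈ 2×2 mm,
~250 spots, 400 genes) are chosen for desk-scale runtime, far below a real
11×11 mm capture area with ~18 000 genes.

Not emulated: H&E morphology, read-level sequencing noise, isotope
interference physics, serial-section deformation (the true homography is
exactly planar), spatial autocorrelation in the gene-specific noise, and
cell-type-driven expression structure (couplings are planted directly on
element fields). Passing tests therefore demonstrate correctness of the
statistical machinery and recoverability of planted effects at realistic
geometry and noise — not performance on real tissue.

## Numerical choices

- Zero-variance guards use a relative 1e-12 tolerance (a "constant" array's
  floating-point SD is ~1e-16, never exactly 0).
- Permutation p-values use the +1/+1 correction, so the floor at
  n_perm = 999 is exactly 1/1000.
- Volcano p-values are floored at 1e-300 before −log10.
- Intensities are float32 on disk, float64 in computation; counts are
  integers end to end (MTX written with the integer field).
- All pipeline TSVs are written with a fixed float format, and one global
  seed fans out to per-stage seeds by CRC-32 of the stage name, so a rerun
  with the same config is bitwise reproducible and adding a stage never
  perturbs earlier stages' randomness.

## Problem sizes

The test suite validates the Gi* implementation against a scalar
brute-force oracle on 200 random instances (n ≤ 200), the correlation
screen's operating characteristics at G = 2000 genes × 1500 spots (200 null
replicates for family-wise error, 20 planted replicates for power), and
end-to-end truth recovery over 20 seeds of the default generator scenario.

## Known limitations

- The stripe detector assumes near-axis stripes; rotated acquisitions
  would need the angular gate widened or the map deskewed first.
- The in-fill median estimates the local background from the perpendicular
  window; stripes crossing sharp genuine boundaries will blur them within
  the ±2 px stripe band.
- Homography refinement assumes a planar section pair; nonrigid
  deformation between serial sections is out of scope.
- The screen's t-approximation p-values are slightly conservative at heavy
  tie loads (low counts); the family-wise error stays below the nominal
  0.05 in the null study.
- EMMs come from an ordinary one-way model; spatial autocorrelation of
  spots is not modelled, so architecture p-values describe association
  strength, not independent evidence.
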