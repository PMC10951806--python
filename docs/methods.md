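# Methods

This note records the statistical models implemented in `spatcorr`, the
parameter choices that matter, the numerical decisions, and what the
synthetic test data do and do not establish about real multiplex images.

## Setting and null model

A sample is a marked point pattern: N points x_i in a rectangular domain D
(coordinates in μm), each carrying an optional categorical mark c_i (cell
type) and any number of continuous marks m_i (stain intensities; NaN means
"absent for this point"). The null model throughout is complete spatial
randomness (CSR), realized as a binomial process: per-mark point counts are
held fixed at their observed values and locations are i.i.d. uniform on D.
Conditioning on counts matches how an observed pattern is compared with its
own randomization and makes all ratio statistics calibrate to 1 without
estimating an intensity. The homogeneous intensity estimate is λ̂_C =
N_C/|D|.

Empirical statistics of this kind measure co-intensity, not causal
correlation: points may co-occur because they respond to shared tissue
structure. Significance should be judged against CSR simulation envelopes
(`csr_envelope`), which return pointwise quantiles across simulated
patterns; pointwise 95% envelopes are exceeded at ~5% of radii by chance
even under the null.

## Edge correction

All pairwise statistics divide each pair's contribution by the area of the
annulus [r, r+ε) around the *first* point that lies inside D. The
disc–rectangle intersection area is computed in closed form: the area of
{X ≤ x, Y ≤ y} ∩ disc is assembled from antiderivatives of the half-chord
√(r²−X²), and the rectangle is recovered by inclusion–exclusion over its
four corners. The computation is exact to floating-point rounding (tests
compare against a 0.1 μm pixel-counting oracle at relative error < 1e−3)
and vectorizes over points × radii, which is what makes the PCF-family
statistics deterministic and fast. Points on the domain boundary are inside
(closed rectangle). Because only the first point of a pair is
edge-corrected, g_AB and g_BA differ through boundary terms alone; they
coincide exactly when all points are at least r+ε from every edge (tested).

## PCF and cross-PCF

g_AB(r) = |D|/(N_A N_B) Σ_{i∈A} Σ_{j∈B} 1[d_ij ∈ [r, r+ε)] / A_ε(x_i, r).
With A = B, self-pairs are excluded and the normalization is N_C(N_C−1);
this choice makes cross_pcf(C, C) identical to pcf(C) and gives expectation
1 under CSR (both tested, the latter at N = 1000 over 20 seeds within
±0.05). Radial grids default to r ∈ [0, 300] μm with Δr = ε = 10 μm — a
scale range suited to cell-diameter (~20 μm) through multi-cluster
structure in 1 mm² regions — and are fully configurable, including
overlapping (ε > Δr) or gapped (ε < Δr) annuli. Pair enumeration uses a
k-d tree with cutoff r_max + ε, so cost scales with the number of
geometrically relevant pairs rather than N².

## TCM

Γ_i = [n_B(x_i, r) / A_r(x_i)] / (N_B/|D|) is the disc-analogue of a
point's cumulative (K-function-type) contribution to the cross-PCF up to
distance r. Γ is linearized by

    Γ′ = min(Γ, α) − 1        for Γ ≥ 1
    Γ′ = 1 − min(1/Γ, α)      for 0 < Γ < 1,   Γ′(0) = −(α−1)

so that k-fold enrichment and k-fold depletion sit symmetrically at
±(k−1), Γ′(1) = 0, and the scale saturates at ±(α−1). The saturation
constant α is the maximal fold change the map resolves; the default α = 5
keeps a single extreme cell from dominating the raster. The surface sums
unnormalized Gaussian kernels (peak amplitude Γ′_i) of width σ at the A
points; σ defaults to r/2 so the ~2σ kernel support matches the radius at
which correlation was measured, and the raster (default 10 μm spacing) is
anchored at the domain's lower-left corner, boundaries inclusive. Defaults
r = 50 μm (two to three cell diameters), all overridable. A point carrying
both marks never counts itself in n_B. The surface is exactly linear in
its single-point kernels and bounded by (α−1)·N_A (both tested).

## NCF

For marks C_1..C_k, every tuple taking one point per mark is scored by its
minimum enclosing circle (MEC) radius — the radius of the smallest region
containing all k cells, a more informative proximity measure than the
maximum pairwise distance because it responds to every point's location.
Observed per-bin tuple counts are divided by (Π_i N_i)·p(bin), with p the
Monte-Carlo estimate of the CSR MEC-radius distribution from n_samples
uniform k-tuples in the same domain (default 100,000; per-bin Monte-Carlo
standard errors are always reported so users can judge and raise it).
Using the data's own domain for the null absorbs edge effects. Bins with
zero expected count are reported as missing (NaN), never as 0. The default
curve is binned, consistent with the PCF's annuli; a cumulative variant
(counts with radius below the bin's outer edge) is available behind a
flag, as either reading is defensible for ratio-of-counts curves. Tuples
whose maximum pairwise distance exceeds 2·r_max are pruned before any
circle is computed — exact, since the MEC radius is at least half the
largest pairwise distance (pruned and unpruned enumeration are tested to
agree). MEC radii for pairs and triplets are computed by direct vectorized
formulas (diametral circle of the farthest pair when it contains the third
point — which covers all collinear and degenerate cases — else the
circumcircle); general point sets use Welzl's randomized incremental
algorithm, with an exhaustive pairs-and-triples search retained as the
test oracle. For k > 3 the tuple stream falls back to per-tuple Welzl.
Complexity grows as Π_i N_i; r_max (default 300 μm) bounds the work via
pruning.

## wPCF

The triangular kernel w(m, M) = max(0, 1 − |m−M|/δ) has transparent
support: marks further than δ from the target contribute nothing. δ
defaults to one tenth of the observed mark range — small enough to resolve
structure across the range, large enough that W_M = Σ_j w(m_j, M) stays
well populated — and is always recorded in the output metadata; a Gaussian
kernel is available as an option. The surface

wPCF(M, r) = |D|/(N_C W_M) Σ_{i∈C} Σ_{j≠i} w(m_j, M)·1[d_ij ∈ bin]/A_ε(x_i, r)

sums j over every point with a finite value in the continuous column
(points without the mark cannot be weighted); self-pairs are excluded.
Rows with W_M = 0 are missing (NaN), not zero. Default target grid: 101
evenly spaced values over the observed mark range. The two-continuous
variant weights both pair ends with per-column δ values (the two ranges
may differ substantially) and normalizes by W_{M1} W_{M2}; its default
target grids are coarser (26 per axis) because the output is a 3-D block.
The wPCF is invariant to affine rescaling of the mark when targets and δ
are rescaled identically, and collapses exactly to the corresponding
cross-PCFs when marks are concentrated at discrete levels and δ is below
the inter-level gap (both tested).

## Synthetic generators

The generators are first-class, tested code and define the study
conditions for every calibration result.

*Dataset I* (two types, 1000×1000 μm): on the left half, 20 cluster
centers drawn uniformly, each receiving 10 points of C1 *and* 10 of C2
from isotropic Gaussians; on the right half, 10 centers per type drawn
independently. Totals are exactly 300 per type. Each C2 point carries a
continuous mark keyed on the *point's own* x coordinate (not its parent
center's): uniform on [0, 0.5) left of the midline, uniform on [0.5, 1]
right of it — so the mark distinguishes mixed-cluster from pure-cluster
cells while remaining a per-cell quantity, as a stain intensity would be.

*Dataset II* (three types): three cluster centers at (350,350), (650,350),
(500,610) — a triangle of side ≈300 μm — with 25 points per type per
cluster. The `pairwise` variant assigns types (A,B), (B,C), (A,C) to the
clusters (50 per type); the `triplet` variant assigns all three types to
every cluster (75 per type).

Cluster standard deviation defaults to 25 μm for both datasets. With these
choices the smallest three-type neighbourhood in the pairwise variant has
radius ≈(300 − 4σ)/2 = 100 μm up to Gaussian tails (empirically ≥ ~85 μm
across seeds), so the NCF is exactly 0 at the 50 μm bin and rises to ~1
over r ∈ [100, 300] — the designed contrast with the triplet variant,
whose NCF exceeds 100 at cluster scale while the two variants' cross-PCFs
are statistically indistinguishable at short range. Gaussian offspring
falling outside the domain are resampled rather than clipped, keeping
per-type counts exact without boundary pile-up. All generators are
deterministic given their seed.

What the synthetic data do not emulate: cell-size exclusion (real
centroids cannot overlap; a hard-core null would shift small-r behaviour),
anisotropic tissue architecture, intensity-dependent segmentation error,
and mark noise correlated with local density. Passing calibration on these
patterns validates the estimators' algebra and normalization, not the
biological interpretation of any particular image.

## Lattice sampling

`lattice_sample` places one point at the center of each spacing×spacing
cell (offset spacing/2, so the lattice is symmetric under image flips —
registration is otherwise arbitrary), carrying the nearest-pixel intensity
as a continuous mark and, given a threshold, a positive/negative
categorical mark. This supports wPCF analysis of channels for which no
segmentation exists; the wPCF of a lattice pattern at high target
intensity reproduces the shape of the cross-PCF of its thresholded
version (tested on synthetic two-channel blobs).

## Numerical choices and degenerate inputs

- MEC containment tolerance: 1e−9 relative to the radius.
- Circumcircle construction falls back to diametral circles when the
  determinant is below 1e−14 × scale² (near-collinear triples).
- Duplicate coordinates are allowed everywhere; an all-identical tuple has
  MEC radius 0 and lands in the first bin.
- Distance bins are half-open [r, r+ε); a pair can enter several annuli
  when ε > Δr, and bin membership at edges tolerates ~1e−12 relative fuzz.
- Curves report NaN (missing), never 0, wherever a ratio's denominator is
  zero; a single-point pattern yields an all-missing wPCF surface.
- CSR envelopes require n_sims ≥ 19 (the minimum for a two-sided 5%
  pointwise band) and derive per-simulation seeds from one seed via
  `SeedSequence`, so envelopes are reproducible bit-for-bit.

## Problem sizes

Calibration computations use 1000-point CSR patterns (20 replicates) for
the PCF and 100,000 Monte-Carlo tuples for the NCF null — sizes at which
the remaining simulation noise is an order of magnitude below the
tolerances being checked, while a full run of the test suite and the
acceptance script completes in well under a minute on one CPU.

## Known limitations

- Rectangular domains only; no masks or periodic boundaries.
- Homogeneous CSR null; inhomogeneous PCF variants are out of scope.
- The NCF's tuple enumeration is Π_i N_i in the worst case; r_max pruning
  makes clustered data tractable but dense patterns with thousands of
  points per type will be slow.
- TCM surfaces are reported as raw kernel sums; no level-set or
  topological summarization is provided.
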