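# spatcorr

Spatial correlation statistics for marked point patterns from multiplex
imaging.

Multiplex immunohistochemistry produces images in which every cell can be
located (a centroid, in μm) and labelled — categorically (cell type) and/or
continuously (mean stain intensity). `spatcorr` quantifies how those cell
populations are arranged relative to one another: do T helper cells cluster
with macrophages, at which length scales, where in the tissue, and do three
or more types co-occur in the same neighbourhoods or only pairwise?

All statistics are ratios against complete spatial randomness (CSR): a value
of 1 means "as expected by chance", above 1 clustering, below 1 exclusion.

## Statistics

**Pair correlation function (PCF / cross-PCF).** For marks A, B with
N_A, N_B points in a rectangular domain D, the empirical cross-PCF on the
annulus [r, r+ε) is

```
g_AB(r) = |D| / (N_A N_B) · Σ_{i∈A} Σ_{j∈B} 1[d_ij ∈ [r, r+ε)] / A_ε(x_i, r)
```

where A_ε(x_i, r) is the annulus area clipped to the domain (exact
closed-form edge correction). With A = B, self-pairs are dropped and the
normalization is N_C(N_C−1), recovering the ordinary PCF. Pointwise CSR
simulation envelopes are available for significance assessment.

**Topographical correlation map (TCM).** A spatially resolved version of the
cross-PCF: each A point gets a local mark Γ_i — the ratio of the B density
within radius r of it (disc-area edge-corrected) to the global B density —
which is linearized to Γ′ (Γ=1 ↦ 0, symmetric fold changes, saturation at
±(α−1)) and spread over the domain as a Γ′-scaled Gaussian kernel of width
σ. The summed raster maps where the two types attract or avoid each other.

**Neighbourhood correlation function (NCF).** For k ≥ 2 marks, every k-tuple
(one point per mark) is summarized by the radius of its minimum enclosing
circle. The NCF is the ratio of observed tuple counts per radius bin to the
count expected under CSR, with the null estimated by Monte-Carlo sampling of
uniform k-tuples in the same domain (edge effects cancel by construction).

**Weighted PCF (wPCF).** Replaces the exact-match indicator of the cross-PCF
with a triangular kernel w(m, M) = max(0, 1 − |m−M|/δ) on a continuous mark
m, giving a surface over (target mark M, radius r). A two-continuous-marks
variant weights both ends of each pair.

Synthetic generators (Thomas-type Gaussian cluster patterns and CSR) are
included, so every statistic can be exercised without external data, and a
lattice sampler converts intensity rasters into point patterns for
segmentation-free analysis.

## Worked example

Two three-type cluster patterns that pairwise statistics cannot tell apart:
in the `pairwise` pattern every cluster holds two of the types A, B, C (all
pairs co-occur, the three types never do); in the `triplet` pattern every
cluster holds all three.

```python
import numpy as np
from spatcorr import generate_dataset_2, cross_pcf, ncf, RadialGrid

grid = RadialGrid(r_start=0, r_max=300, dr=10)   # 10 μm annuli
pair = generate_dataset_2(seed=0, variant="pairwise")
trip = generate_dataset_2(seed=0, variant="triplet")

g = cross_pcf(pair, "A", "B", grid)
print(np.round(g.value[1:5], 2))        # [25.89 29.79 19.46 15.  ]

n_pair = ncf(pair, ["A", "B", "C"], grid, n_samples=100_000, seed=1)
n_trip = ncf(trip, ["A", "B", "C"], grid, n_samples=100_000, seed=1)
print(n_pair.value_at(50.0))            # 0.0
print(round(n_pair.value_at(150.0), 2)) # 26.53
print(round(n_trip.value_at(20.0), 1))  # 753.6
```

The cross-PCF reports strong short-range A–B clustering in *both* patterns
(values ≈ 15–40 at r ≤ 40 μm; the triplet pattern prints `[38.1 33.27 26.43
19.24]`). The NCF separates them: in the pairwise pattern no neighbourhood
of radius 50 μm ever contains all three types (value 0.0) and three-type
neighbourhoods only appear once circles span two clusters (value 26.5 at
r = 150 μm), while the triplet pattern shows enormous three-way correlation
at cluster scale (753.6 at r = 20 μm).

The same analyses run from the shell:

```bash
spatcorr synth dataset2-pairwise --seed 0 --out d2.csv
spatcorr ncf --input d2.csv --marks A,B,C --samples 100000 --seed 1 \
         --domain 0,1000,0,1000 --out ncf.csv
```

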