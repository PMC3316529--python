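# Methods

This note documents the models and procedures implemented in `tissuetensor`,
the assumptions behind them, the defaults that matter, and the choices made
where the design was genuinely open.

## 1. Cell-graphs

A tissue sample is reduced to a *cell-graph* G = (V, E): one node per nucleus
centroid (micron coordinates over a bounded field), edges encoding spatial
proximity.

**Node identification (segmentation).** RGB images are converted to La\*b\*
(perceptually uniform, separating luminance from chroma) and clustered by
k-means (k = 2 by default, 10 restarts, fixed seed stream).  Clusters are
assigned to cell/background either automatically (lowest-luminance cluster =
cell, appropriate for hematoxylin-dark nuclei) or by an explicit map.  The
binary mask is averaged over a square grid (`grid_size` pixels, default 4);
each grid entry becomes a cell-probability.  Border entries are averaged over
the covered pixels only, so probability mass is conserved exactly.  Entries
*strictly greater* than a threshold — Otsu's maximizer of between-class
histogram variance by default, or a fixed value — become foreground; each
8-connected (configurable to 4) component is one nucleus, and its centroid is
reported at `(index + 0.5) * grid_size * microns_per_pixel`.

**Edge establishment.** Deterministic linking connects every pair with
`d(u,v) <= t`; the canonical thresholds are 65, 70 and 75 µm, the approximate
radii of spread mammalian cells.  We use the inclusive comparison so the
integer thresholds behave identically on integer-micron coordinates; a
`strict_less` flag restores the strict inequality.  Probabilistic linking is
also provided: each pair is linked independently with probability
`exp(-d/L)` or `min(1, (d/d0)^-a)`, both clamped to [0, 1] and monotone
non-increasing in distance, with p(0) = 1.  The kernel constants are free
configuration parameters.

## 2. Graph features

Twenty-six features per graph, in a fixed canonical order (connectivity,
distance and compactness indicators plus edge-length statistics and raw
counts).  Conventions, fixed here because the literature uses several:

- **Clustering coefficients.** C = mean Watts–Strogatz local clustering over
  nodes with degree ≥ 2; D = global transitivity (3·triangles / connected
  triples); E = mean local clustering over all non-isolated nodes with
  degree-1 nodes contributing 0.  These are interpretations of three named
  variants whose original definitions live in prior literature; they are not
  claimed to match those exactly.
- **Distance features on disconnected graphs.** Eccentricity, diameter,
  radius and average path length use finite hop distances only (within
  connected components); isolated nodes have eccentricity 0.  This avoids
  infinities while preserving monotonicity.
- **"90" variants.** ecc90(v) is the smallest hop count covering ≥ 90% of the
  nodes reachable from v; diameter90/radius90 are its max/min.  Consistent
  with the 90%-quantile convention of the effective hop diameter.
- **Hop plot.** N(h) counts ordered reachable pairs within h hops.  The hop
  plot exponent is the log–log least-squares slope over hops with
  N(h) < N(∞); the effective hop diameter is the smallest h with
  N(h) ≥ 0.9·N(∞), linearly interpolated between integer hops and floored
  at 1.
- **Central points** are nodes whose finite eccentricity equals the radius.
- **Edge-length statistics** (mean, std, skewness, kurtosis) use population
  normalization; kurtosis is Pearson (non-excess, normal ≈ 3).
- **Spectral extras** (optional): spectral radius, the log–log slope of the
  top 20% of descending adjacency eigenvalues ("eigen exponent"), and the
  zero-eigenvalue count of the normalized Laplacian, which equals the number
  of connected components (zero tolerance `1e-8·n`).  The normalized
  Laplacian spectrum lies in [0, 2], making differently sized graphs
  comparable.

Empty graphs yield all-NaN features with a warning; edgeless graphs yield
NaN for distance and edge-length features.  The default exclusion list drops
*effective hop diameter*, *number of central points* and *percent central
points* (identified as outliers), leaving 23 features for factorization.

## 3. Factorizations

**SVD.** Thin SVD with explained-variance fractions σᵢ²/Σσ²; truncation to K
components is the best rank-K approximation (Eckart–Young).

**Matricization.** Mode-n unfolding places mode n on the rows and flattens
the remaining modes with the first of them varying fastest, so
`unfold(X, 0) = A (C ⊙ B)ᵀ` for X = [[A, B, C]] with ⊙ the column-wise
Khatri–Rao product.

**CP (CANDECOMP/PARAFAC).** X ≈ Σᵣ λᵣ aᵣ∘bᵣ∘cᵣ, fitted by alternating least
squares: each factor matrix in turn is the exact least-squares solution given
the others, so the fit `100·(1 − ‖X − X̂‖/‖X‖)` is non-decreasing across
sweeps.  Stopping: relative fit change < 1e-9 or 500 sweeps; 3 restarts by
default (random init; optional HOSVD init for the first restart), best fit
kept, all randomness from one seed.  Scale/sign indeterminacy is fixed by
unit-norm columns with non-negative weights λᵣ; each non-leading mode's
columns are sign-fixed so their largest-magnitude entry is positive, and the
residual sign lands in the leading mode (forcing the sign convention in all
modes simultaneously is incompatible with λᵣ ≥ 0 in general).

**Core consistency.** Given a fitted CP model, the least-squares Tucker core
G (weights absorbed into the leading mode) is compared with the superdiagonal
identity: `100·(1 − ‖G − I‖²/R)`.  Values near 100 support the rank; strongly
lower or negative values indicate over-factoring.  Two normalizations exist
in the literature (divide by R vs by ‖G‖²); the R-divisor is used.  At an ALS
fixed point the R = 1 diagnostic is exactly 100.  Note that over-factoring
low-noise data occasionally yields a negligible extra component (weight ≈ 0)
with high consistency; across repeated simulations the median diagnostic
collapses far below 50, which is what the recovery experiments report.

**CMTF.** The coupled objective
`f(A,B,C,D) = ‖X − [[A,B,C]]‖² + ‖Y − A Dᵀ‖²` shares the features-mode
factor A between a 3-way tensor and a matrix.  The analytic gradient with
respect to each factor is concatenated and the problem is solved by nonlinear
conjugate gradient (Polak–Ribière with Wolfe line search, via
`scipy.optimize.minimize(method="CG")`), gradient-norm stopping scaled by
‖X‖² + ‖Y‖².  The two terms are unweighted, matching the objective as
stated.  The first restart is initialized from a CP fit of the tensor plus
the least-squares D; remaining restarts are random; the lowest objective
wins.  Degenerate solutions are flagged when any component pair's multi-mode
congruence (product over modes of cosine similarities) falls below −0.85
(configurable), the signature of two ever-growing, mutually cancelling
components.

**Factor match score.** Recovery of planted factors is scored by the best
component assignment (Hungarian algorithm) of the mean-over-components
product-over-modes absolute cosine similarity — invariant to permutation,
sign and scale.

## 4. Results-level procedures

- **Tensor assembly**: feature tables keyed by (sample, time) fill a
  (features × samples × time) tensor; any missing or duplicated cell is an
  error (complete designs only, no imputation).
- **Preprocessing**: feature-wise centering/scaling to unit sd.  The
  projection procedure prescribes scaling by the *histology* statistics; for
  CP/CMTF the z-scoring default is a documented interpretation (the
  factorizations accept raw data via `scale=False`).
- **Separation** is quantified, not judged visually: per component, the
  misclassification count of the best single threshold (exhaustive over
  realizable cuts and both polarities — tied scores cannot be split) plus a
  between/within variance ratio; significance is assessed against a
  label-permutation null (200 shuffles, α = 0.05).
- **Influential features**: ranked by |coefficient| in the separating
  component; top 5 reported by default.
- **Source clustering**: per class, the tensor matricized in the features
  mode is concatenated with the histology matrix, standardized and factored
  by SVD; the first two components' scores are labeled by source and their
  linear separability quantified, with the explained variance of those two
  components reported.
- **Cumulative variance curves** per class/source with a merge index: the
  first component from which two curves stay within 0.02.
- **Time-course projection**: in vitro columns are standardized with the
  histology transform and projected onto the first two histology left
  singular vectors; the per-time mean distance to the histology score
  centroid tracks how closely the culture approaches native organization.

## 5. Synthetic data: what it emulates, and what it does not

No imaging data are bundled; every experiment runs on generators with known
ground truth.

- **Spatial patterns**: a Poisson-parent / Gaussian-offspring cluster process
  (Matérn-like).  Parents fall at `cluster_rate` per mm² (drawn over the
  field expanded by a 4·`cluster_sd` guard band to avoid edge effects), each
  with Poisson(`intensity`/`cluster_rate`) offspring displaced by isotropic
  Gaussian(`cluster_sd` µm) noise and thinned to the field.  Defaults:
  healthy 120 nuclei/mm², 30 clusters/mm², 60 µm dispersion; cancer 300/mm²,
  45/mm², 30 µm — denser and more clumped, a qualitative contrast knob, *not*
  an estimate of any real tissue's statistics.
- **Time course**: 5 samples × 11 time points (0–168 h), intensity scaled by
  `1 + drift·t/168` (default drift 0.5) to emulate monotone densification
  from gel compaction.
- **Rendering**: nuclei become filled discs (default radius 9 µm at
  3 µm/pixel) in a dark foreground on a light background with i.i.d. Gaussian
  pixel noise; 5% noise means sd 12.75 on the 0–255 scale.  No attempt at
  realistic H&E color statistics, overlapping nuclei, or illumination
  gradients — passing segmentation tests shows the chain is self-consistent,
  not that it handles real stain variability.
- **Low-rank data**: factor matrices i.i.d. standard normal with unit-norm
  columns; noise is additive Gaussian scaled to a stated *relative Frobenius
  norm*.  Coupled data share the first-mode factor exactly.  Class structure
  can be planted in chosen sample-mode components (class means ±gap/2, jitter
  sd 0.25); a border-rank construction
  (a₁∘b₁∘c₂ + a₁∘b₂∘c₁ + a₂∘b₁∘c₁) provides the canonical degenerate-fit
  scenario.  Over-factoring plain low-rank data, by contrast, usually yields
  a benign near-zero or positively-correlated extra component rather than the
  degeneracy signature.

All generators are bit-reproducible given (seed, parameters); pipeline
stages draw named substreams from one root seed.

## 6. Problem sizes and numerical choices

The analysis drivers and recovery experiments use desk-scale sizes chosen to
exercise every code path with comfortable statistical margins: tensors of
shape (23, 20, 11) or (23, 10, 11), histology matrices with 20–24 samples,
10-seed recovery replicates, 200-shuffle permutation nulls, and 100-graph
spectral/oracle sweeps.  Tolerances: ALS fit change 1e-9; CMTF gradient norm
1e-10 relative; zero-eigenvalue tolerance 1e-8·n; rank-deficiency guard on
the core-consistency pseudo-inverses at 1e-12 relative singular value.

## 7. Known limitations

- Segmentation has no watershed splitting: touching nuclei merge into one
  node.  No stain normalization or morphology features.
- 2-D only; no multi-node-type graphs.
- Clustering-coefficient variants C/D/E, the "90" quantile features, the
  effective hop diameter and the eigen exponent are documented
  interpretations of names whose defining formulas appear only in prior
  literature.
- The real histology/in vitro image collections behind the original analyses
  are not publicly deposited, so their reported explained-variance
  percentages are not reproduction targets; all quantitative claims here are
  about planted synthetic structure.
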