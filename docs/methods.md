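# Methods

This note documents the models and procedures `griddiv` implements,
the defaults and why they were chosen, what the synthetic worlds do
and do not emulate, and the numerical decisions a maintainer should
know about.

## Grid and data model

All layers live on a rectangular lon/lat grid (`GridSpec`), indexed
0-based and row-major with row 0 northernmost; cell size is nominally
0.5°. Geographic metadata stays in `GridSpec`; every analysis operates
on flat cell ids, which keeps CRS machinery out of the core. Presence
matrices are binary (presence–absence only; nothing here is
abundance-weighted). Undefined cells — outside the biome mask, or
below the richness a metric needs — are NaN, never zero.

## Synthetic worlds

The generator produces worlds with the statistical structure the
analysis assumes, so that every downstream stage can be validated:

- **Phylogeny** — a coalescent-style construction (random pair merges
  at exponential waiting times, rescaled to unit height) gives a
  rooted, binary, ultrametric tree. Unit height means branch lengths
  and BM rates are in comparable units across world sizes.
- **Traits** — quantitative traits evolve by Brownian motion (child =
  parent + N(0, σ²·branch)); categorical traits by a symmetric k-state
  Markov chain (closed-form transition probabilities). Defaults mirror
  an amphibian-style schema: three quantitative traits
  (snout–vent length, head width, tibia length) and two categorical
  ones (development mode; tadpole ecomorph with three states).
- **Missingness** — a fraction of species (default 16.5%, the level at
  which the imputation machinery is calibrated) each lose at least one
  quantitative value, uniformly at random. Real missingness is usually
  biased toward rare species; the generator does not emulate that, so
  passing recovery tests speak to the missing-at-random regime only.
- **Climate** — each layer is Gaussian-kernel-smoothed white noise
  (kernel sd = `spatial_range` cells), standardised at the present
  day, with an optional per-slice mean drift and optional independent
  per-slice noise; slice ages run 120, 116, …, 0 kyr BP, 31 slices for
  the default horizon. This is a stationarity caricature: real
  paleoclimate has trends, spatial non-stationarity and correlated
  layers, none of which are modelled. An optional fixed west–east
  gradient on a layer lets biome bands be made climatically separable
  (used by the classifier demonstrations).
- **Terrain** — slope is the central-difference gradient magnitude,
  aspect the compass direction of the downhill gradient (degrees
  clockwise from north; an eastward-rising ramp faces due west, 270°),
  roughness the max-minus-min of the 3×3 neighbourhood; edges use the
  truncated neighbourhood.
- **Biomes** — contiguous vertical bands (optionally
  boundary-perturbed, always 8-connected) with an optional "outside"
  band on the right to support pseudo-absence sampling.
- **Ranges** — each species' niche optimum is itself a BM trait on the
  tree (so range overlap is phylogenetically structured); a species
  occupies the largest 8-connected patch of cells within
  `niche_breadth` of its optimum, falling back to the single best cell
  so ranges are never empty.

Everything is deterministic given its seed; the pipeline derives
per-stage seeds from a master seed by hashing the stage name, so any
stage can be reproduced in isolation.

## Diversity metrics

**SES-MPD / NRI.** Observed MPD is the mean over unordered within-cell
pairs of cophenetic distances. The null holds richness fixed and draws
species from the regional pool without replacement (default 999
draws, drawn independently per cell — sharing draws across cells of
equal richness would leave each cell's statistics unchanged but
correlate their errors and bias pool-level summaries). Cells with
fewer than two species are undefined. NRI ≡ −SES exactly; both are
kept because users differ in which sign convention they regress.
A community equal to the whole pool has a degenerate null; its SES is
0 by convention, and null sds below 1e-10 (float summation noise on
identical draws) are treated as zero.

**Blomberg's K.** K is the ratio of observed to Brownian-expected
MSE₀/MSE, with the mean estimated by phylogenetic GLS. Significance
comes from comparing the variance of standardized independent
contrasts against tip-shuffled nulls (lower observed variance =
signal), with the +1 rank correction. Polytomies are resolved with
zero-length edges before computing contrasts; a zero-length cherry
contributes a zero contrast (its tips are perfectly correlated).

**Maddison–Slatkin.** Minimum parsimony steps by Fitch on a
binary-resolved copy (zero-length resolution does not change the
minimum); p is the lower-tail rank among tip-shuffled nulls. A
single-state trait returns 0 steps, p = 1, not an error.

**Imputation.** Tips are jointly Gaussian with covariance kron(R, C):
C the BM phylogenetic covariance (shared root-to-MRCA path lengths), R
the among-trait evolutionary covariance. R and the ancestral means are
estimated by EM over the missing entries (conditional expectations and
covariances in the E-step; GLS mean and trace-corrected cross-products
in the M-step); missing values are finally replaced by their
conditional expectation. No measurement error, no model selection
across evolutionary models — Brownian motion only. Positive
semi-definite C (zero-length cherries) is ridged by the smallest
diagonal jitter that makes Cholesky succeed, capped at ~1e-4 of the
diagonal scale; genuinely indefinite input raises. The procedure is
invariant to species order and to affine trait rescaling (up to EM
tolerance), and on BM-simulated data beats species-mean imputation in
≥95% of replicates at 16.5% missingness.

**Functional space.** Gower dissimilarity averages range-normalised
quantitative differences and 0/1 nominal mismatches, all traits
equally weighted (weights are configurable; zero-range traits are
dropped with a warning). PCoA square-roots the dissimilarities first
— mixed-data Gower matrices are not metric, and the square root bounds
negative eigenvalues near zero; axes with eigenvalue > 1e-10 are kept.
Decoupling regresses each functional axis (with intercept) on
phylogenetic eigenvectors from a PCoA of the cophenetic distances
(no correction needed there: ultrametric distances embed exactly) and
keeps the residuals. FDis is the unweighted mean distance of present
species to their centroid; single-species cells are 0, empty cells
NaN.

*Eigenvector retention.* With a complete tree the phylogenetic PCoA
yields n−1 positive axes, and regressing on all of them saturates the
fit, forcing FDis to zero identically. The low-level `decouple`
follows the retain-all convention with a configurable cap; the
pipeline caps predictors at the leading axes carrying 95% of the
positive eigenvalue mass (`phylo_axes_mass`), which preserves the
dominant phylogenetic structure while leaving residual trait variance
estimable. This retention rule is a genuine design choice; no
authoritative rule exists.

## Climatic stability

One binary random-forest per biome (presences = biome cell centroids,
pseudo-absences sampled uniformly without replacement from the region
outside every modelled biome), 500 trees, √p features per split,
out-of-bag accuracy reported. Variable importance mirrors the usual
two-column report: permutation importance (mean decrease in accuracy,
computed on the training set — the ensemble's OOB machinery does not
expose per-variable permutation, so this is the package's stand-in
convention) and Gini importance. The fitted model is projected onto
each slice; the fraction of trees voting presence is dichotomised at
0.5 (majority vote; configurable — the overlay rule for turning
probabilistic projections into counts is not standardised) and the
binary maps are summed: stability ∈ [0, n_slices], 31 for the default
horizon. With zero temporal drift and a deterministic ensemble the
layer is all-or-nothing {0, 31}. An optional greedy Chebyshev-distance
thinning of presence points exists but is off by default (no thinning
distance is authoritative).

## Spatial models

**Screening.** VIF_j = 1/(1−R²_j) from regressing predictor j on the
rest (with intercept); the highest-VIF predictor is dropped
iteratively until all VIF ≤ 3. Perfect collinearity shows as infinite
VIF and is resolved the same way, ties broken by column order.
Survivors are z-scored over the analysis cells.

**Adjacency.** "Immediately adjacent" is read as queen (8-neighbour)
adjacency, consistent with the 8-neighbourhood ecotone rule; rook is
available. Weights are binary and symmetric — the CAR variance form
requires symmetry — not row-standardised. Isolated cells are flagged,
not dropped.

**CAR.** y = Xβ + u with Cov(u) = σ²(I − ρW)⁻¹, fitted by maximum
likelihood: for fixed ρ, β and σ² have closed GLS forms, so the
profile likelihood is optimised over the admissible interval
(1/λ_min, 1/λ_max) of W's eigenvalue spectrum by bounded scalar
search. Every profile evaluation is O(p²) because all ρ-dependent
quadratic forms are linear in precomputed cross-products; the spectrum
is computed once per adjacency and cached. Convergence within ~1e-5 of
the interval boundary triggers a warning. Standard errors come from
the GLS information σ²(X′QX)⁻¹ and p-values from asymptotic
z-statistics. R²_KC is the squared Pearson correlation between y and
the full prediction Xβ̂ + ρ̂W(y − Xβ̂); it equals classical R² exactly
when W is empty, in which case the whole fit collapses to OLS with
ρ = 0. On simulated CAR lattices (20×20, 500 replicates) the 95%
intervals cover the true slopes at 93–97% and slope bias is < 0.05.
Standardized OLS betas (coefficients on z-scored y and X) are computed
separately for cross-predictor comparison; with one predictor the
beta is the Pearson correlation.

The pipeline fits one CAR and one OLS per biome × metric on the cells
where the metric is defined, with the focal biome's own stability
layer among the candidate predictors (it drops out automatically when
constant within the biome, e.g. under zero climate drift).

## Ecotones

Ecotone cells: focal-biome cells with ≥1 of 8 neighbours in the
named adjacent biome, computed by shifting the neighbour mask one step
in all eight directions (no wraparound) — verified exactly equal to a
per-cell neighbourhood scan. Core cells: focal cells farther than a
Chebyshev buffer (default 3 steps; 4 and 5 are config options) from
every differently-labelled biome cell; cells outside all biomes do not
count as boundary by default. The permutation test compares the mean
FD of the ecotone against means of ecotone-sized samples from the
core — without replacement when the core is at least as large, with
replacement otherwise — 9999 permutations, +1-corrected p-values
(never zero). The upper tail is primary (the working hypothesis is
ecotones exceed cores); a two-sided p and a percentile bootstrap 95%
CI of the mean difference (9999 resamples of both sets) are also
reported. Because the null resamples the core only, the test is
exactly calibrated in the limit of a core much larger than the
ecotone and becomes anti-conservative as the two sizes approach
(finite-population narrowing of the null); the calibration suite
therefore checks type-I error in the thin-fringe/large-interior
regime in which the test is used.

## Pipeline defaults and problem sizes

The default synthetic world is a 20×24 grid (4 outside columns), 60
species, 3 biomes, 31 slices, spatial range 3 cells, drift 0.05,
niche breadth 1.2, 16.5% trait missingness. Analysis defaults: 199
SES-MPD nulls and signal randomisations, 999 ecotone permutations and
bootstrap resamples, 200 trees (the classifier demonstrations and the
acceptance computation use the full 500). These sizes keep a complete
run in seconds while leaving every statistic far from its asymptotic
breakdowns; all counts are config knobs, and the conventional
full-scale values (999 nulls, 9999 permutations, 500 trees) are the
documented defaults of the underlying functions.

## Known limitations

- CAR fitting is dense in the adjacency spectrum (one symmetric
  eigendecomposition per lattice); fine to a few thousand cells,
  not designed for continental 0.5° grids in one block.
- The imputation EM builds the full kron(R, C) joint; cost grows as
  (n_species × n_traits)³ in the worst case.
- No abundance weighting anywhere; FRic/FEve/RaoQ are out of scope.
- Tree uncertainty is not propagated; a single tree is taken as known.
- Polygon rasterisation is O(cells × species) point-in-polygon work —
  adequate at desk scale, not optimised.
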