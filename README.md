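# griddiv

Multi-facet diversity analysis for gridded species assemblages.

`griddiv` is aimed at macroecologists who work with range maps
superimposed on a regular (0.5°-style) grid and want to ask how
taxonomic, phylogenetic and functional diversity respond to present-day
environment, topography and long-term climatic stability — and whether
biome transition zones (ecotones) hold more functional diversity than
biome interiors. Every stage runs on synthetic worlds generated inside
the package, so the full pipeline is testable without any external
data.

## What it computes

Per grid cell, from a presence matrix, a dated ultrametric phylogeny
and a mixed quantitative/categorical trait table:

- **TD** — species richness.
- **PD** — the standardized effect size of mean pairwise phylogenetic
  distance, SES-MPD = (MPD_obs − mean MPD_null) / sd MPD_null, with an
  equal-richness null drawn from the regional species pool, and its
  sign-flipped form the net relatedness index, NRI = −SES. Positive
  NRI = phylogenetic clustering; the metric is independent of richness
  by construction.
- **FD** — functional dispersion (FDis): the mean distance of
  co-occurring species to their community centroid in a trait space
  built from Gower dissimilarities (square-root corrected PCoA) and
  *decoupled* from the phylogeny by regressing each functional axis on
  phylogenetic eigenvectors and keeping the residuals.
- **Climatic stability** — a random-forest biome classifier (500
  trees, √p candidate predictors per split) trained on biome presences
  versus pseudo-absences, projected across 31 paleoclimate slices
  (120 kyr at 4-kyr steps); stability is the per-cell count of slices
  predicted suitable, from 0 (maximally unstable) to 31.

Missing quantitative trait values are imputed under a multivariate
Brownian-motion model (EM-estimated trait covariance, phylogenetic
covariance from shared branch lengths); phylogenetic signal is
quantified with Blomberg's K (contrast-randomisation p-values) for
quantitative traits and the Maddison–Slatkin parsimony test for
categorical ones.

Diversity surfaces are regressed on VIF-screened (threshold 3),
z-scored predictors with Gaussian **conditional autoregressive (CAR)
models** fitted by maximum likelihood on the grid adjacency,
summarised by the Kissling–Carl R² (squared correlation of the
observations with trend + spatial signal); standardized OLS betas are
reported alongside. Ecotone cells (focal-biome cells touching another
biome in the 8-neighbourhood) are compared with core cells (beyond a
3-step Chebyshev buffer) by a permutation test that resamples
ecotone-sized cell sets from the core (9999 permutations, with
replacement only when the core is smaller), with percentile-bootstrap
CIs on the mean difference.

## Worked example

Run the whole pipeline on the built-in synthetic world (20 × 24 grid,
60 species, 3 biome bands plus an outside region, 31 climate slices):

```bash
griddiv run-all --seed 42 --out demo_out
```

or in Python:

```python
from griddiv.pipeline import PipelineConfig, run_pipeline

bundle = run_pipeline(PipelineConfig(seed=42, output_dir="demo_out"))
print(bundle.missingness)
# {'n_species': 60, 'n_missing': 10, 'percent_missing': 16.7}
print(bundle.signal_tests)
#         trait  statistic            method  p_value
#           svl   0.718947        blomberg_k    0.005
#    head_width   1.230900        blomberg_k    0.005
#  tibia_length   1.869190        blomberg_k    0.005
#   development   8.000000  maddison_slatkin    0.005
#       tadpole   2.000000  maddison_slatkin    0.005
```

Ten of 60 species (16.7%) were simulated with missing quantitative
values and imputed before analysis. All five traits carry significant
phylogenetic signal, as expected for Brownian-evolved traits (K near
1) and Markov-evolved states (8 observed parsimony steps for
`development`, far below its shuffled null).

The CAR table (`demo_out/car_models.csv`) holds one row per biome ×
metric × predictor; for biome 1 and TD the fitted model reports
ρ = 0.133 and Kissling–Carl R² = 0.82 (OLS R² = 0.67 — the spatial
component absorbs the rest), with the synthetic richness gradient
loading on the temperature layer (β = 3.64, p ≈ 5e-21). The ecotone
table shows, for each ordered biome pair, the ecotone-minus-core FDis
difference with its bootstrap CI and permutation p-values; in this
world biome 1's fringe is *less* functionally dispersed than its core
(difference −0.016, 95% CI [−0.022, −0.009], two-sided p = 0.002), a
reminder that the sign of the ecotone effect is a property of the
world, not of the method.

All outputs (layers, tables, Newick tree, MANIFEST with seeds and
hashes) land in `demo_out/`; rerunning with the same config reproduces
the bundle bit-for-bit.

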