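# morphoclade

Phylogenetic comparative analysis of 3-D landmark shape data, built for
studies that ask how ecology — habitat, diet, trophic level — shapes the
tempo and mode of morphological evolution across a clade. The motivating
application is the evolution of shark lower jaws, where CT-derived
landmark configurations on ~90 species are combined with candidate
phylogenies and diet/habitat tables to test for habitat-mediated
diversification; the package reimplements that entire analysis chain as
a tested, scriptable library with a synthetic-data generator, so every
stage runs and is verifiable without any external downloads.

## What it computes

Given specimens × landmarks (TPS or CSV), trees (Newick/NEXUS) and an
ecology table, the pipeline provides:

- **Superimposition** — generalized Procrustes analysis with sliding
  semilandmarks (thin-plate-spline bending-energy criterion; curve
  points slide along tangents, surface points within tangent planes),
  centroid sizes CS = √Σᵢ‖xᵢ−x̄‖², and species-mean shapes.
- **Ordination & signal** — PCA and phylogenetically aligned component
  analysis (eigenanalysis of the data's cross-product with its
  projection through the tree covariance C); multivariate phylogenetic
  signal K_mult (the Blomberg ratio of deviations in ordinary vs
  C-whitened space against its Brownian expectation) with permutation
  tests; axis retention by a sequential eigenvalue log-likelihood-ratio
  test; mechanical-advantage and symphysis-depth proxies.
- **Phylogenetic linear models** — penalized-likelihood multivariate GLS
  with Pagel's λ / early-burst / OU covariance transforms (ridge-shrunk
  trait covariance chosen by cross-validated likelihood, built for
  p ≫ n), type-II permutation MANOVA/MANCOVA with Wilks' Λ, trait-model
  selection by an information criterion, and ML ancestral shapes.
- **Trophic ecology** — Bray–Curtis diet dissimilarities, UPGMA feeding
  guilds, LP/MP/TP trophic categories.
- **Discrete evolution** — Mk likelihoods (ER/SYM/ARD) by pruning, AIC
  model choice, marginal ancestral states, and stochastic character
  mapping by endpoint-conditioned uniformisation.
- **Rates & disparity** — regime-specific Brownian rates σ²ₖ from
  character maps (species covariance Σₖ σ²ₖ Cₖ), per-landmark rates,
  fold-change reporting, Procrustes-variance disparity with bootstrap
  Wilcoxon tests, and disparity-through-time curves against a Brownian
  envelope.
- **Rate-shift MCMC** — a reversible-jump sampler for branch-specific
  rate scalars on retained ordination axes, a regime-rate posterior
  sampler pooled over character maps, and R̂/ESS convergence reports.

## Worked example

```python
import numpy as np
from morphoclade import (SimulationSpec, simulate_study, gpa,
                         average_by_species, pca, kmult, fit_mk, simmap,
                         regime_bm_rates, rate_fold_changes,
                         group_disparity)

spec = SimulationSpec(n_species=40, n_extra_specimens=10, seed=42)
specimens, ecology, trees, truth = simulate_study(spec)

aligned = gpa(specimens, slide=True)          # GPA + sliding
species = average_by_species(aligned)         # species-mean shapes
tree = trees.summary_tree

ord_ = pca(species.matrix)
print(f"PC1 explains {ord_.percent_variance[0]:.1f}% of shape variance")

sig = kmult(species.matrix, tree, species.species, n_perm=999, seed=42)
print(f"K_mult = {sig.k_mult:.3f} (p = {sig.p_value:.3f})")

habitat = {r.species_id: r.habitat for r in ecology}
tips = {sp: habitat[sp] for sp in species.species}
mk = fit_mk(tree, tips, "ER", seed=42)
maps = simmap(tree, tips, mk.Q, n_maps=5, seed=42)
rates = regime_bm_rates(species.matrix, species.species, maps)
for rg, r in sorted(rates.rates.items(), key=lambda kv: -kv[1]):
    print(f"  sigma2[{rg}] = {r:.3e}")
```

Output:

```
PC1 explains 23.1% of shape variance
K_mult = 0.570 (p = 0.001)
  sigma2[deep-sea] = 3.608e-05
  sigma2[reef] = 2.330e-05
  sigma2[shelf] = 1.707e-05
  sigma2[pelagic] = 8.163e-06
```

The synthetic study plants its highest Brownian rate scalars in the
deep-sea and reef regimes; the fitted regime rates recover that
ordering, the significant K_mult reflects the Brownian structure of the
simulated shapes, and `rate_fold_changes(rates.rates)` turns the σ²
values into the ratio table used for reporting (here deep-sea/shelf
≈ 2.1). Per-habitat disparity from `group_disparity` ranks deep-sea
highest (PV = 0.0037 vs 0.0025 for pelagic in this run).

## Command line

```bash
morphoclade full --seed 1 --out run1           # synthetic end-to-end
morphoclade align --config cfg.yaml --out run1 # individual stages
```

Stages: `simulate`, `align`, `ordinate`, `signal`, `guilds`, `rates`,
`disparity`, `dtt`, `full`. Each writes plain CSV/TSV/JSON artefacts
plus a JSON run manifest with seeds and input digests.

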