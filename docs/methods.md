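# Methods

This note documents the models, numerical choices and limitations of the
morphoclade pipeline in the order the stages run.

## Superimposition

Generalized Procrustes analysis removes translation (centering), size
(scaling to unit centroid size, CS = sqrt of summed squared landmark
deviations from the centroid) and rotation (SVD-based orthogonal
Procrustes with the determinant forced to +1; reflections are disallowed
by default because landmark correspondences are biologically homologous,
`allow_reflection=True` overrides). The consensus is the arithmetic mean
of the aligned configurations, renormalised each pass; iteration stops
when the summed squared distance to the consensus changes by less than
`tol` (default 1e-8, `max_iter` 100).

Semilandmarks slide against the current consensus to minimise
thin-plate-spline bending energy. The 3-D TPS kernel is U(r) = r; the
bending-energy matrix is the upper-left block of the inverted TPS system,
symmetrised and sign-fixed so the quadratic form is positive
semi-definite. Curve points move along tangents estimated by central
differences of their curve neighbours (the curve list supplies order;
endpoints are anchored on fixed landmarks); surface points move within
the plane of the two leading principal directions of their 6 nearest
consensus neighbours. The joint linearised step solves the standard
normal equations in the allowed-direction basis; the step is halved until
the energy is non-increasing, so a sliding pass can never raise the
energy. Three slide passes interleaved with full re-alignment are the
default. Two deliberate divergences from mesh-based practice: slid points
are not re-projected onto a surface mesh (no meshes in scope), and
collinear consensus anchors produce a singular TPS system that is
regularised with a warning.

## Ordination and phylogenetic signal

PCA is an SVD of the column-centred species (or specimen) matrix; axis
signs are fixed by making the largest-magnitude loading positive.
The phylogenetically aligned component analysis centres the data on the
GLS (phylogenetic) mean and takes the eigenvectors of Z'·H C H·Z, the
cross-product of the centred data with its projection through the
(column-centred) tree covariance C, so leading axes maximise variation
aligned with phylogenetic signal; explained percentages are reported
against total data variance, and with C ∝ I the axes reduce to ordinary
PCA.

K_mult is the multivariate Blomberg statistic: the ratio of summed
squared deviations from the phylogenetic mean in ordinary versus
C-whitened space, divided by its Brownian expectation
(tr C − n/(1'C⁻¹1))/(n−1). Significance comes from permuting species
across tips; p = (b+1)/(n_perm+1). K_mult is invariant to global data
scaling and to tree-wide branch-length scaling (both verified by test).

The number of meaningful axes uses a sequential Anderson sphericity
(log-likelihood-ratio) test on the eigenvalue spectrum at α = 0.05: the
smallest k whose trailing eigenvalues are statistically homogeneous. It
is reliable when observations comfortably exceed dimensions; with n ≲ p
the Marchenko–Pastur spread inflates the statistic.

Mechanical advantage is in-lever / out-lever with configurable landmark
indices (out-lever: articular-condyle anchor to anterior symphysis
anchor; in-lever: condyle to the centroid of adductor-insertion surface
points). Inter-landmark levers are a rough functional proxy, not a
biomechanical model.

## Phylogenetic linear models

Y (n species × p traits, typically p ≫ n for 3p Procrustes coordinates)
is matrix-normal with row covariance C(θ) — Brownian motion; Pagel's λ
(off-diagonals × λ); early burst with C_EB = (e^{rC} − 1)/r, r ≤ 0; or
the stationary OU transform — and trait covariance Σ estimated by linear
ridge shrinkage toward its diagonal, Σ(δ) = (1−δ)S + δ·diag(S). The
shrinkage intensity is chosen by leave-one-out cross-validated Gaussian
log-likelihood over a 10-point grid (0 plus log-spaced to ~0.9); θ is
optimised by bounded scalar search. Coefficients are GLS estimates in the
whitened space. The information criterion is −2·logLik + 2·df with
df = (coefficients) + (θ parameters) + (1−δ)·p(p+1)/2 + δ·p, an
effective-dimension account of the shrunk covariance; it is a desk-scale
criterion whose model-ranking behaviour (EB recovered on EB data, BM not
spuriously beaten) is verified by simulation rather than a literature
formula.

MANOVA/MANCOVA uses type-II sums of squares: each term is tested by
comparing the model with all other terms (excluding interactions that
contain the target) against that model plus the target, via Wilks'
Λ = |E|/|E+H| in the whitened space. Significance is by Freedman–Lane
permutation of reduced-model residuals. When traits exceed residual
degrees of freedom, traits are first projected onto their leading
principal components so the determinants exist; at test scale (p small)
the statistic is exact and matches the classical closed form on a star
tree. The permutation p convention is (b+1)/(n_perm+1).

Continuous ancestral states are the BM maximum-likelihood (GLS) values:
anc = μ + C_nt C_tt⁻¹ (Y − μ) with μ the GLS root estimate; for a
two-tip tree this is the branch-length-inverse-weighted tip average.
Zero-length cherries are regularised toward equal weights with a warning.

## Trophic ecology

Bray–Curtis dissimilarity on renormalised prey proportions, UPGMA
(average-linkage) clustering via scipy, guild assignment by cutting the
dendrogram at k groups (default k = 8; a largest-height-gap automatic cut
is available but not default). Species with monospecific diets can be
excluded from clustering and labelled by their sole prey category.
Trophic-level bins: TR ≤ 3.8 LP, 3.8 < TR ≤ 4.2 MP, TR > 4.2 TP; the
side of the 4.2 boundary is configurable because published usage varies.

## Discrete characters

Mk likelihoods use Felsenstein pruning with per-branch transition
matrices computed from one eigendecomposition of Q (batched over
branches, with scaling-and-squaring fallback for defective Q) and
per-node partial rescaling. Root priors: equal, stationary, or FitzJohn
(default). Fitting is multi-start Nelder-Mead on log rates, seeded by a
coarse common-rate grid scan — the likelihood has a flat saturated
plateau at high rates that traps gradient-based line searches. AIC uses
the free-rate count (ER 1, SYM s(s−1)/2, ARD s(s−1)).

Stochastic maps sample node states from their joint conditional
distribution (root from the posterior, then preorder children given the
parent state and the subtree partials) and branch histories by
endpoint-conditioned uniformisation: the jump count is drawn from the
truncated Poisson–R-power mixture, the state sequence by
backward-weighted sampling, jump times uniformly, and self-transitions
collapsed. Maps are reproducible per (seed, map index); per-map segment
durations always tile the branch lengths (asserted on every sampled map).

## Rates, disparity, disparity through time

Regime-specific rates: the expected species covariance is
Σ_k σ²_k C_k, with C_k the shared branch length spent in regime k of a
character map. Relative scalars (reference regime fixed at 1) are
optimised by Nelder-Mead on the profile likelihood in which per-trait
variances are profiled out analytically; the reported per-regime rate is
the mean of the regime rate-matrix diagonal across traits (median
available). Scalars are bounded to e^±11.5 so regimes with negligible
exposure cannot diverge; regimes occupying < 1% of tree length are
flagged unstable. Summaries aggregate over a pool of maps (mean, SD).
Per-landmark rates sum each landmark's three coordinate rates; they
decompose exactly to 3p × the scalar rate.

Procrustes variance is the summed per-coordinate variance around the
group mean (divisor n). Bootstrap resamples species within groups with
replacement (optional rarefaction to the smallest group size); pairwise
comparisons use two-sided Wilcoxon rank-sum tests on the bootstrap
distributions with Bonferroni correction over pairs. Bootstrap PV is
biased low by roughly (n−1)/n, visible in the consistency test.

DTT evaluates, at each internal-node height, the mean relative disparity
of the tip sets below every lineage crossing that time (singletons
contribute 0), normalised so the root value is 1. The null envelope
comes from Brownian simulations rate-matched per trait to the data
(2.5/97.5 percentiles per time point); the reported area statistic is
the integral of observed minus simulated mean over relative time.
Ultrametry is required and checked.

## Rate-shift MCMC

The variable-rates model evolves each retained ordination axis
independently (axes are orthogonal scores) by BM on a tree whose branch
b has effective length r_b·t_b. The per-axis likelihood is the
linear-time contrast (REML) form, which is invariant under
t → c·t, σ² → σ²/c; a consequence is that the two children of a
bifurcating root are informed only through their summed scaled lengths,
so scalars there are confounded with their siblings — planted-shift
experiments therefore exclude root-adjacent branches. Priors: geometric
shift count (p = 0.5) with uniform placement, log-uniform scalars on
[1e-3, 1e3], wide uniform log global rates. Moves: global-rate walk,
scalar walk, and birth/death with prior draws; with these proposals the
reversible-jump acceptance reduces to the likelihood ratio times the
geometric count ratio. Desk-scale defaults are 2×10⁵ iterations, 25%
burn-in, thinning 20, 2 chains; traces are bit-reproducible per
(seed, chain). Clade-wide scalar moves are not implemented.

The regime-rate sampler shares the contrast likelihood with effective
lengths Σ_k σ²_k·(regime-k duration), per-axis scale factors (first axis
as reference), and mixes random-walk with prior-independence proposals.
Chains cycle over the supplied pool of character maps so reconstruction
uncertainty widens the pooled posterior. Pairwise summaries report
P(σ_A > σ_B) and the overlap proportion 2·min(P, 1−P), with < 0.05 the
conventional separation call. Note that for equal-rate regimes and
informative data, P(σ_A > σ_B) is approximately uniform across data
replicates (a property of any calibrated posterior), so the meaningful
null guarantee is the nominal false-separation rate of the 0.05 overlap
rule, which is what the tests check.

Convergence: rank-normalised split R̂ and autocorrelation ESS via arviz,
with the usual R̂ < 1.1 and ESS > 200 thresholds.

## Synthetic data

The generator produces what the analysis assumes: a pure-birth tree
scaled to unit height; habitat regimes under an equal-rates Mk process
(rate 0.5 per unit height, four states); species shapes as the jaw-like
template (100 landmarks on a bent half-tube: 6 fixed anchors, two curves
with 51 interior sliding points, 43 surface points) plus multivariate
BM/EB displacements with regime scalars; specimens as species shapes
plus isotropic digitisation noise (SD 0.004 in template units, template
CS ≈ 7) under random similarity transforms so alignment has work to do;
and Dirichlet diet compositions with planted guilds (concentration 12 on
the focal prey). Default regime scalars 7.7 (deep-sea), 5.4 (reef),
1.5 (pelagic), 1.0 (shelf) mirror the habitat rate ordering and ratios
the pipeline is designed to detect. The default study size is 90 species
and 145 specimens; tests run smaller (12–64 species) replicas of the
same process.

What the generator does not emulate: mesh geometry and projection
artefacts, correlated (non-isotropic) digitisation error, missing
landmarks, fossil tips, and tree-estimation error beyond supplying
multiple trees. Passing tests therefore demonstrate correctness of the
estimators under the stated models, not robustness to those real-data
pathologies.

## Degenerate inputs and tie-breaking

Coincident landmarks give CS = 0 and a domain error at log CS; rank-<2
configurations are rejected by name; SVD rotation signs are fixed via
determinant +1; UPGMA ties break to the lowest cluster index (scipy
convention); constant trait matrices warn and return zero eigenvalues;
single-observed-state Mk data return a lower-bound rate with a warning;
zero-variance MCMC axes are dropped with a warning.
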