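# Methods

This note documents the models, numerical choices and design decisions
behind `warmnet`, and what the synthetic experiments do and do not show.

## Study design emulated by the generator

A randomized block design: 4 blocks × 5 warming levels (ambient control,
+0.8, +1.5, +3.0, +4.2 °C above ambient), each treatment exactly once per
block, sampled at two depth layers (0–10 cm topsoil, 10–20 cm subsoil) —
20 samples per layer. Responses are parameterized on the warming-offset
axis (not treatment rank). Treatment coefficients are attenuated by a
factor 0.15 in the subsoil, reflecting the expectation that warming
effects concentrate in the topsoil; block random intercepts and residual
noise are not attenuated.

## Synthetic abundance model

**Marginals and closure.** Taxon abundances are log-normal: a latent
standard-normal value per taxon × sample (scaled by an idiosyncratic
log-sd of 0.45), plus a per-taxon baseline (sd 1.0 across taxa) and
treatment-dependent log-scale multipliers, exponentiated and closed to
relative abundances per sample. Relative abundances below a detection
limit (5·10⁻⁴) are zeroed and the sample re-closed, emulating finite
sequencing depth. The idiosyncratic sd of 0.45 is deliberately milder than
the heaviest amplicon data: with 40 taxa and 20 samples, heavier tails let
single-taxon spikes dominate per-sample composition and drown the
abundance-weighted cohesion ratio in weight noise.

**Planted rank correlation.** Modules are planted through a Gaussian
copula: one latent factor per module, member loadings √r with
r = 2·sin(πρ_s/6) converting the target Spearman ρ_s to the latent Pearson
correlation. The exponential marginal is monotone, so Spearman targets are
preserved exactly in expectation. Negative-sign modules split members into
two anti-correlated halves (sign-alternating loadings): all-pairwise
negative equicorrelation is not positive semidefinite for more than two
members, so within-half pairs are positive and cross-half pairs negative;
the recorded planted-sign matrix reflects this. A module's `latent_scale`
shrinks or widens members' latent spread without changing planted
correlations (used to let a shared treatment trend, rather than a latent
factor, carry a guild's internal correlation).

**Default community structure.** Each community (40 nematode taxa, 40
protist taxa; counts configurable — the study's post-filtering taxon
numbers are not fixed by the design, so these are explicit assumptions)
contains:

- a large static clique (ρ = 0.9; 16 nematode / 13 protist taxa): the
  dense, always-present network core;
- a static seesaw of two anti-correlated cliques (ρ = 0.9, negative;
  8 taxa): persistent negative edges;
- a small thermophilic counter-guild (4 taxa) whose internal correlation
  comes from its shared treatment trend (no latent factor,
  latent_scale 0.4) and whose mass share rises from ~2 % at ambient to
  ~35–60 % at +3.0 °C, falling back at +4.2 °C;
- "ephemeral" cool-adapted taxa (12 per community, high per-taxon noise
  sd 2.0) that sit near the detection limit: mostly present at ambient,
  mostly undetected around +3.0 °C, partially back at +4.2 °C, with
  negligible mass.

**How the planted truths produce the three warming humps.** These choices
were driven by two structural constraints discovered during design:
(i) compositional closure converts any large guild mass swing into a
shared spurious trend across *all* other taxa (their relative abundances
mirror the swing), and (ii) the positive-semidefiniteness of correlation
matrices forbids strongly net-negative large modules. Within those
constraints:

- **Connectance** humps at +3.0 °C because the ephemeral taxa contribute
  nodes but almost no edges (their mutual correlations are diluted by the
  large per-taxon noise): when present, they dilute the dense core and
  depress connectance; their presence dips exactly where warming peaks.
- **NPC** (|negative|:positive cohesion) humps because the counter-guild
  is trend-anti-correlated with the ephemerals, giving it strong negative
  and weak positive connectedness; its mass peak at +3.0 °C raises
  |C_neg|/C_pos there.
- **MNC** humps because the ten nutrient-pool variables follow quadratic
  response curves with vertex at +2.8 °C and peak amplitude ≈ 2 residual
  sd, making +3.0 °C the largest sampled mean with a visible drop at
  +4.2 °C.

Functional-group multipliers (mild declines for bacterivores, mild
increases for omnivores/predators, ephemeral behaviour for herbivores,
predators and protist parasites) provide the per-group effect-size
responses analysed in the inference layer.

**RNG discipline.** The master seed spawns independent child streams for
the design, each community and the soil table, so adding taxa to one
community perturbs nothing else. All outputs are bit-reproducible given
the seed.

**What the generator does not emulate.** Sequencing reads, OTU/ASV
calling, primer bias, within-plot spatial structure, phylogenetic
relatedness, or temporal autocorrelation. Passing tests show the analysis
machinery recovers known structure from compositional, detection-limited,
rank-correlated data at the study's sample size — not that real microfauna
data satisfy the generator's assumptions.

## Network construction

- **Prevalence filter**: taxa nonzero in ≥ 25 % of a layer's samples
  (configurable). Spearman correlation on near-constant rows is unstable;
  the original analysis does not state a filter.
- **Spearman matrices**: average ranks for ties; two-sided p-values from
  the t approximation with n − 2 df (adequate at n = 20); constant rows
  are recorded as missing and excluded from edge sets.
- **BH adjustment** is applied to the upper-triangle p-values only.
- **RMT threshold selection**: the threshold grid runs 0.30–0.99 in steps
  of 0.01. At each threshold, entries with |ρ| below it are zeroed,
  isolated taxa dropped, and the spectrum unfolded by a cubic
  least-squares spline fit to the empirical spectral CDF (interior knots
  at quantiles, ~1 knot per 15 eigenvalues; exact degeneracies collapsed
  first). Spacings are rescaled to unit mean (a mean outside [0.8, 1.2]
  flags a degenerate unfolding) and tested by chi-square against the
  Poisson law and the Wigner surmise, with Sturges bins merged until every
  expected count is ≥ 5. The selected threshold is the smallest whose
  Poisson p-value exceeds 0.05 for three consecutive grid points — the
  persistence rule guards against single-point chi-square flukes. If no
  threshold qualifies, an explicit error carries the full diagnostic
  trace; the pipeline can fall back to a configured threshold. Only the
  spline unfolding is implemented (Gaussian broadening was considered and
  dropped: one well-tested method was judged better than two half-tested
  ones).
- **Edges** require both |ρ| ≥ threshold *and* BH-adjusted p < 0.05 — the
  strictest consistent composition of the two published criteria. Signs
  follow the correlation sign; isolated taxa remain as flagged
  degree-0 nodes.

At the study's sample size (n = 20), sampling noise alone reaches
|ρ| ≈ 0.6–0.75, so the FDR criterion is usually the binding filter and
the RMT scan often accepts Poisson statistics low on the grid (the
thresholded matrices are block-diagonal once modules dominate). On denser
data (e.g. n = 200 planted-module matrices or the pooled 80-taxon tables)
the selected thresholds rise toward the 0.6–0.9 range familiar from
RMT-thresholded field studies.

## Per-sample metrics

Subnetworks are induced on taxa with abundance strictly > 0 (no minimum
abundance cutoff). All topological metrics ignore signs and weights:
average degree 2E/N, connectance 2E/(N(N−1)), mean local clustering
(nodes of degree < 2 contribute 0), global efficiency as the mean inverse
unweighted shortest-path length over ordered pairs (disconnected pairs
contribute 0; computed by BFS via `scipy.sparse.csgraph`, cross-checked
against networkx in tests). Vulnerability is the maximum proportional
efficiency loss over single-node removals, with the reduced graph's
efficiency normalized over its own (N−1)(N−2) ordered pairs — the exact
removal normalization is an implementation choice worth stating, since
some published implementations keep the original N. Graphs with fewer
than 3 nodes, or zero efficiency, yield flagged degenerate records.

## Cohesion

Cohesion uses the full community abundance table (not only network
nodes): it is abundance-weighted and threshold-free by construction.
Correlations inside cohesion are Spearman for internal consistency with
network construction (the classical cohesion method used Pearson; a
config switch restores it). The null model permutes each partner column
independently ("taxa shuffle", 200 iterations by default, seeded);
corrected correlation = observed − null mean, computed for *ordered*
pairs, so the corrected matrix is asymmetric. Connectedness averages the
strictly positive (strictly negative) corrected correlations per taxon;
sample cohesion weights these by relative abundance, and
NPC = |C_neg|/C_pos, flagged undefined when C_pos = 0. With 20 samples
the null-corrected floor is substantial (mean strictly-signed noise
correlations ≈ ±0.2); NPC contrasts therefore ride on abundance-weighted
differences between guilds, which is exactly what the generator plants.

## Multinutrient cycling index

Averaging multifunctionality index: z-score each variable within the
standardization cohort (all 20 samples of a depth layer, matching the
within-layer treatment contrasts), then average across variables per
sample. The default variable set is the ten C/N/P pools (SOC, TN, TP, AP,
NH₄-N, NO₃-N, DOC, MBC, MBN, MBP); soil temperature and moisture are
treated as drivers elsewhere and excluded from the index. Zero-variance
variables are dropped with a warning; an all-constant cohort raises an
error. The index is exactly location/scale invariant per variable and has
cohort mean 0.

## Inference layer

- **Effect sizes**: Gaussian linear mixed models with the warming level as
  a categorical fixed effect (ambient as reference) and block random
  intercepts, fit by REML (statsmodels `MixedLM`). The treatment factor
  is tested with the Wald type II χ² — with a single categorical
  predictor this is the joint Wald test of all treatment coefficients.
  The asymptotic χ² reference is anticonservative with 4 blocks and 20
  plots (empirical size ≈ 0.12 at nominal 0.05), so reported p-values are
  calibrated against F(q, n − p − (g − 1)) with between-within denominator
  degrees of freedom; the statistic itself remains the Wald χ².
  Empirical size under this calibration is ≈ 0.04–0.05. Zero estimated
  block variance is reported as such (the fit then equals OLS), never a
  silent failure; a constant response returns all-zero effects.
- **Shape selection**: degree-1 vs degree-2 fits on the warming-offset
  axis (centered), by ML for AIC comparability (REML likelihoods are not
  comparable across fixed-effects structures). AIC counts all variance
  parameters; the OLS path adds the residual-variance parameter so both
  paths share one convention. Selection is decisive when ΔAIC > 2;
  "unimodal" requires a winning quadratic opening downward with its
  vertex strictly inside the observed range. Exactly collinear or
  noiseless inputs short-circuit (quadratic skipped with a warning;
  perfect linear fits select linear directly, since the Gaussian ML
  log-likelihood diverges).
- **Hierarchical variance partitioning**: the marginal R²
  (Nakagawa–Schielzeth: fixed-effects variance over fixed + block +
  residual variance; fitted-value variance with ddof = 1) is decomposed
  into per-predictor contributions by the exact subset formula with
  hierarchy weights |S|!(k−|S|−1)!/k! over all 2^k subsets (k capped at
  13). Predictors are standardized first; rank-deficient subsets are
  reduced to independent columns before fitting (fitted values, hence
  R², are unchanged). Contributions telescope to the full model's
  marginal R² for *any* set function, so additivity is exact; agreement
  with the k!-orderings average additionally requires stable subset fits —
  the profile likelihood is nearly flat in the block variance for these
  designs, so subset fits run two optimizers and keep the better
  likelihood. Per-predictor significance comes from the full REML model's
  coefficient z-tests.
- **Link models**: "generalized" linear mixed models with a continuous
  response are implemented as Gaussian identity-link models (no family is
  implied by a continuous index). Linear and quadratic candidates are
  compared by ML AIC; the winner is refit by REML for reporting, with a
  95 % confidence band from the fixed-effects covariance over the
  observed predictor range only.
- **Multiple testing** across the many response metrics is *not*
  adjusted; stars are per test, mirroring standard practice in this
  literature. Interpret accordingly.

## Pipeline

Networks are built per community × depth layer across all 20 samples of
the layer (treatments pooled) — the default 3 communities × 2 layers
yields 6 networks — and treatment contrasts are carried by the per-sample
subnetworks. The full run emits TSV tables for networks, per-sample
metrics, stability, MNC, effect sizes, shapes, partitions and links, plus
a JSON report with the config hash; identical configs reproduce identical
bytes. Hierarchical partitioning in the default pipeline uses six
pre-screened drivers (SM, ST, SOC, MBC, MBN, MBP) rather than all 13 soil
variables: exact enumeration is 2^k mixed-model fits per response, and six
drivers keep the default run interactive while the full set remains one
config entry away.

## End-to-end evaluation sizes

The end-to-end check runs 50 seeded pipeline replicates (topsoil, both
taxonomic communities, effect-size inference) and asks how often the
+3.0 °C effect size is the largest among warming levels for connectance,
NPC and MNC. The network-metric pattern is summarized per replicate as
the mean β across the nematode and protist analyses — the experiment-level
summary; single communities carry substantial realization noise at
n = 20 (per-community rates ≈ 0.77–0.85, experiment-level ≥ 0.9). The
pooled whole-microfauna table is not used for this summary: pooling
halves the core clique density (cliques do not span communities) while
the ephemeral taxa's shared treatment trends do, which erases the
connectance contrast. Mixed-model calibration uses 500 replicates; shape
selection 200; spectral statistics one 500×500 GOE matrix and one
500-level uncorrelated spectrum.

## Known limitations

- Cohesion connectedness estimates at n = 20 are noisy; guild-level
  contrasts are reliable, per-taxon values are not.
- The RMT transition on 40-taxon, 20-sample matrices often sits at the
  low end of the grid; the FDR criterion then dominates edge selection.
- The Wald small-sample calibration uses between-within denominator df, a
  pragmatic choice (Kenward–Roger is not available in the underlying
  mixed-model implementation).
- Functional-group effect directions in the defaults are internally
  consistent with the planted network mechanisms rather than tuned to any
  particular field system.
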