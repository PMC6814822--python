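# Methods

This note documents the models implemented in `ssdevol`, their assumptions,
the tunable parameters and defaults, the synthetic-data generator, and the
numerical choices made where the design was genuinely open. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Dimorphism index and regimes

Sexual size dimorphism is measured by the size dimorphism index

    SDI = ±(S_L / S_S − 1) · 100   [percent],

where `S_L` and `S_S` are the mean body masses of the larger and smaller
sex; the sign is positive when males are larger. Equal masses give exactly
0 (the sign convention is then irrelevant). SDI is stored and modelled in
percent, so every OU optimum Θ below is in percent as well. The index is
antisymmetric under swapping the sexes and invariant to rescaling both
masses, and these properties are property-tested.

Species carry two categorical axes: social system
(`territorial_solitary`, `pair_living`, `group_living`, `variable`) and diet
(`carnivory`, `omnivory`, `insectivory`, `herbivory`, `aquatic_carnivory`).
For multi-optima modelling the 4 × 5 grid collapses deterministically to six
combined regimes: pair-living and variable groups pool with group-living,
and insectivory, herbivory, and aquatic carnivory pool into "other". The
loader takes categories as given and never reclassifies a species;
borderline natural-history calls (e.g. lions as territorial-solitary) are
data-entry decisions made upstream of this package.

## Phylogenetic RMA and the Rensch's-rule test

Rensch's rule predicts male-biased SSD increases with body size, i.e. an
RMA slope of ln male on ln female mass above 1. We orient the regression as
y = ln male, x = ln female so that slope > 1 reads directly as a positive
Rensch trend.

The bivariate trait vector is modelled as matrix-normal with row covariance
C(λ) — the Brownian tree covariance with off-diagonals scaled by Pagel's λ —
and an unstructured 2 × 2 rate matrix R. Given λ, the phylogenetic means are
GLS, R profiles out in closed form, and λ is maximized on [0, 1] by bounded
scalar search on two sub-intervals plus endpoint checks (tolerance 1e-6),
which avoids boundary traps. Evolutionary (co)variances are the GLS residual
cross-products divided by n − 1; the slope is `sign(s_xy)·sqrt(s_yy/s_xx)`
with standard error `|b|·sqrt((1−r²)/(n−2))`.

The slope test follows Clarke (1980) as used in standard phylogenetic RMA
software: `T = |ln b − ln b₀| / sqrt((1−r²)/(n−2))` referred to a
t distribution with effective df `2 + (n−2)/(1 + r²/2)` (non-integer; about
0.65 n at r² ≈ 0.95). Significance is called at α = 0.05. Perfectly
correlated traits make the bivariate likelihood unbounded; the slope and
intercept remain defined and are returned with r² = 1. Per-clade fits prune
the tree to the clade's species; clades below 3 species are skipped with a
warning.

## Mk models and stochastic character mapping

Discrete regimes evolve by a continuous-time Markov chain with generator Q
(rows sum to zero). Structures: ER (one rate, the default — matching the
default of the mapping software this module interoperates with), SYM, and
ARD. The likelihood is computed by Felsenstein pruning with per-branch
transition matrices `exp(Qt)`; symmetric generators are diagonalized once
and all branches evaluated in a single batched product. Rates are estimated
by bounded L-BFGS-B on log rates (bounds 1e-9 to 1e4 per Myr, multi-start at
0.1×, 1×, 10× a total-tree-length heuristic). A character with no observed
variation drives the rate to the boundary and is flagged. The root prior
defaults to uniform and is configurable.

Stochastic maps are drawn with Q fixed at its ML estimate (empirical Bayes):
node states are sampled from their joint conditional distribution given the
tips (root-to-tip), then each branch history is drawn by **uniformization**
conditioned on its endpoints — the jump count comes from the exact
endpoint-conditioned Poisson mixture, jump states from the backward
recursion over powers of `R = I + Q/μ`, and jump times are uniform order
statistics. Uniformization bounds the work per branch, so runtime is
deterministic at desk scale, unlike rejection sampling. Zero-length branches
carry a single zero-duration segment. Sampled maps always satisfy the
segment-sum and parent/child continuity invariants, which are validated on
construction.

The simmap text dialect stores per-branch segments as
`{state,duration:state,duration:...}` ordered **rootward → tipward**; the
interoperating dialect never declares its order, so this package's parser
and writer fix and enforce that convention.

Map summaries report per-node state frequencies (fraction of maps in each
state at each node) and mean transition counts per ordered state pair, where
a "count" is the number of change events painted on the tree (a state
regained after an excursion counts each event).

## Ornstein–Uhlenbeck models of SDI

Three model classes are compared on the SDI vector:

- **BM1** — Brownian motion; parameters: root mean, σ² (p = 2).
- **OU1** — single optimum; parameters: α, σ², θ (p = 3).
- **OUM** — one optimum per mapped regime with shared α and σ²
  (p = 2 + k). Multi-α / multi-σ² variants are out of scope.

The tip covariance uses the non-stationary-root OU form
`V_ij = σ²/(2α)·e^(−α d_ij)·(1 − e^(−2α t_ij))` (`d_ij` patristic distance,
`t_ij` shared time), with the α → 0 limit handled analytically as σ²C. The
expectation at a tip is Hansen's exponentially discounted mix of the optima
along its root-to-tip regime history; the root term `e^(−αT)` is **merged
into the ancestral-most regime's optimum** (the common default of the OU
fitting software this mirrors; a separate root optimum is not estimable on
ultrametric trees without strong priors). Weight-matrix rows sum to 1
exactly by telescoping.

Because V(α, σ²) = σ²·V₀(α) and the mean is linear in Θ, both Θ (GLS) and σ²
(ML closed form) profile out analytically, reducing each fit to a
one-dimensional search over log α: a 24-point log-spaced grid spanning
half-lives from 20× tree depth down to depth/500, refined by bounded scalar
search between the best grid point's neighbours (xatol 1e-4 on log α).
Bootstrap refits narrow the bracket around the parent fit's α. α is floored
at 1e-10/Myr and an ill-conditioned V₀ receives 1e-10 diagonal jitter with a
warning. Fitting is deterministic.

Model comparison across stochastic-map replicates: BM1 and OU1 are
map-independent and fitted once; each OUM variant is refitted on every map.
AICc = −2lnL + 2p + 2p(p+1)/(n−p−1). **Per-map Akaike weights are averaged
across maps** — not recomputed from mean AICc values — and the reported
ΔAICc is on mean AICc. A map whose fit fails is dropped with a warning; more
than 10% failures is an error. The phylogenetic half-life is ln 2 / α
(reported as infinite for BM-like fits).

Parametric-bootstrap intervals simulate trait vectors from the fitted
Gaussian (W Θ̂, σ̂² V₀(α̂)), refit the same model on the same map, and report
2.5/97.5 percentile bounds; percentile intervals may exclude the point
estimate under skew, and only lower ≤ upper is guaranteed. Replicates whose
refit fails are dropped (more than 20% is an error).

Brownian ancestral states of SDI are the joint-ML (harmonic) estimates —
each internal value the inverse-branch-length weighted mean of its
neighbours — with standard errors from the inverse curvature scaled by the
ML Brownian rate; the root estimate coincides with the GLS phylogenetic
mean.

## RJ-MCMC shift detection

The shift model places K optimum shifts on branches without a-priori regime
assignments: K ~ Poisson(λ = 15) truncated at the branch count and
renormalized; branch subsets uniform with at most one shift per branch;
within-branch position uniform on [0, 1) and **applied at the sampled
position**, not the branch midpoint; each new optimum and the background
optimum θ₀ carry a normal prior. α and σ² are shared tree-wide.

Hyperpriors are weakly informative and scale-aware, centred on the data:
θ, θ₀ ~ N(data mean, (2 × data SD)²); ln α ~ N(ln(ln 2/(depth/3)), 1.5²);
ln σ² ~ N(ln σ̂²_BM, 1.5²).

Moves: birth, death, relocate, θ random-walk, log-α random-walk, log-σ²
random-walk (default mix 0.15/0.15/0.10/0.30/0.15/0.15). Birth draws the new
optimum from its prior, which collapses the reversible-jump acceptance ratio
to `(L'/L)·λ/(K+1)` (death: `(L'/L)·K/λ`); impossible moves (death at K = 0,
birth at K = B) are rejected in place, preserving detailed balance. The
likelihood caches the Cholesky factor of V₀(α) so that all moves except α
updates cost O(n²). With the likelihood held constant (validation mode) the
sampler must — and in the acceptance suite does — reproduce the truncated
Poisson prior on K; for that prior-only validation run the birth/death move
weights are raised to speed K mixing, a sampler setting that leaves the
stationary distribution untouched.

Default run lengths are desk-scale: 200,000 generations, thinned every 100,
two chains, 30% burn-in; production-scale settings (10⁶ generations sampled
every 10⁴) remain available through configuration. Summaries report the
per-branch posterior shift probability pp (fraction of retained samples with
a shift on that branch; the pp values sum to the posterior mean of K), θ
summaries for branches above the pp threshold (default 0.5), Gelman–Rubin R̂
across chains, and autocorrelation ESS (Geyer initial positive sequence,
capped at the trace length; anti-correlated traces are capped rather than
allowed to exceed n; constant traces report n with a degeneracy warning). R̂
is truncated below at 1 — values under 1 arise only from sampling noise, and
identical chains report exactly 1.

## Synthetic-data generator

The generator emulates the statistical shape of the study data:

- **Trees**: pure-birth (Yule) with the requested tip count, rescaled to the
  requested depth. Tree-shape detail beyond that is immaterial to the
  methods under test, so birth–death extensions are not provided.
- **Regimes**: exact Gillespie simulation of the Mk chain down the tree,
  returning the true history and tip states.
- **Traits**: one exact draw from the multivariate normal (WΘ, V) implied by
  the model and map — no Euler discretization error in generated data (the
  Euler–Maruyama path is used only as an independent oracle in tests).
- **Species tables**: ln female mass by Brownian motion (root ln 5000 g,
  rate 0.02 (ln g)²/Myr — carnivoran-scale masses); male mass is
  `female·(1 + SDI/100)` for male-biased species and
  `female/(1 + |SDI|/100)` for female-biased ones, so the index recomputed
  from the masses round-trips exactly. Draws containing SDI ≤ −100 are
  redrawn (practically never at the default settings). The combined regime
  decodes to representative social/diet categories (solitary →
  territorial-solitary, group → group-living, other → insectivory) so the
  coding round-trips through the regime collapse.

The frozen study-shaped recipe (`paper_like_recipe`): 166 species, 60 Myr
depth, six combined regimes with optima Θ = (solitary-carnivory 50,
solitary-omnivory 33, solitary-other 6, group-carnivory 15, group-omnivory
9, group-other 17) percent, phylogenetic half-life 3.16 Myr
(α = ln 2/3.16 ≈ 0.219/Myr), stationary SD 10% (σ² = 2α·100 ≈ 43.9 %²/Myr,
giving an SDI spread of roughly −25% to +85%, mostly male-biased), ER
transition rate 0.003/Myr from a solitary-carnivorous root (≈ 30 regime
changes tree-wide — rare transitions with few reversals). These are
generator settings that define the simulated study conditions, not values
estimated from data.

What passing tests on this generator do **not** show: robustness to
measurement error in masses, intraspecific variance, non-ultrametric or
misdated trees, regime-misclassification, or model misspecification beyond
the classes fitted. Fossil taxa and within-species sampling are out of
scope.

## Pipeline, configuration, and problem sizes

The pipeline chains loading/validation (or synthesis) → SDI and regime
coding → per-clade RMA → stochastic maps for the social, diet, and combined
characters → five-model comparison (BM1, OU1, OUM_social, OUM_diet,
OUM_social_diet) → parametric bootstrap of the best model → RJ-MCMC shifts →
ancestral-state and transition summaries, and writes TSV/CSV/JSON outputs
plus a manifest (config echo, stage runtimes, failure point). All randomness
descends from one master seed through `SeedSequence` spawns; reruns are
byte-identical. Configuration defaults mirror the production analysis scale
(500 maps, 1000 bootstrap replicates, pp > 0.5, 30% burn-in); unknown keys
are rejected with a closest-match suggestion and all value errors are
reported at once.

Tree/table matching uses exact species names after underscore/space
normalization; unmatched rows and tips are dropped and logged. Polytomies
are treated as hard; zero-length branches are allowed.

The acceptance script and test suite run at desk scale, chosen as the
package's own working sizes: 20 stochastic maps, 100 bootstrap replicates
and 2 × 20,000 RJ-MCMC generations in the acceptance script; coverage
checked over 200 datasets × 200 bootstrap replicates on a 48-tip tree;
mapping correctness over 20,000 maps on a 5-tip tree; planted-shift recovery
with 2 × 40,000 generations on a 100-tip tree. The planted-shift check
plants on an interior branch that is not a child of the root and whose
children both subtend several tips: a shift on a root-child branch is not
identifiable, because a shift on its sister plus a shifted background
optimum yields the identical likelihood.

## Known limitations

- OUM assumes a single α and σ² across regimes; rate or constraint
  heterogeneity will load onto the optima.
- The RMA slope test relies on Clarke's approximate effective df; its exact
  finite-sample behaviour depends on the true correlation (type-I error is
  verified near nominal at n = 30, r ≈ 0.9).
- Stochastic maps condition on Q̂ (empirical Bayes); rate uncertainty is not
  propagated beyond the map replicates.
- The RJ-MCMC explores optima-only shift configurations; shifts in α or σ²
  are out of scope, and pp values on short basal branches can be split
  between statistically near-equivalent placements.
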