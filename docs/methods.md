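# Methods

This note records the models, priors, sampler design and numerical choices
made in `phylocoev`, including the package's own "desk-scale" defaults and
known limitations.

## Conventions

- Trees are rescaled to unit root-to-tip depth on load (ultrametric input;
  pendant edges are snapped to exact unit depth to absorb floating-point
  drift). All rate and variance parameters are therefore per total tree
  depth.
- Ordinal traits take levels 0–3 and are modelled by a latent Gaussian
  liability cut at ordered thresholds (probit link).
- Great-circle distances use the haversine formula with a mean Earth radius
  of 6,371.0088 km.
- Phylogenetic uncertainty: every fit function accepts a tree sample and
  assigns chains (signal model) or per-iteration draws (multistate) across
  trees; posterior draws are pooled across trees.

## Distance correlation (`phylocoev.trees`)

Pearson correlation between the condensed upper triangles of the patristic
and great-circle distance matrices, with df = n(n−1)/2 − 2 (for 97 taxa:
4,654), a Fisher-z confidence interval, and a Mantel permutation test
(`method="mantel"`) as the exchangeability-respecting alternative to the
parametric p-value.

## Phylogenetic signal (`phylocoev.signal`)

Bivariate ordinal probit mixed model. For tip i and trait d:

    y_id = k  iff  c_{d,k} < g_id + e_id <= c_{d,k+1}
    vec(g) ~ N(0, Σ ⊗ C),   e_i ~ N(0, R),  R diagonal 1, offdiag ρ_res
    Σ = [[σ²_pol, ρ_phy σ_pol σ_rel], [ρ_phy σ_pol σ_rel, σ²_rel]]

C is the Brownian tree correlation matrix. Signal per trait is
λ_d = σ²_d / (σ²_d + 1).

Priors: log σ_d ~ N(0, 1) on the standard deviation scale (half-normal-like
mass near moderate signal), ρ_phy and ρ_res uniform on (−1, 1) via an
atanh parameterization, cutpoints c ~ N(0, 2) subject to ordering, bounded
to (−8, 8).

Sampler: data-augmented Gibbs (Albert–Chib).

1. Liabilities z: truncated-normal full conditionals, each trait given the
   other through R.
2. Phylogenetic effects g: eigendecomposition of C turns the Kronecker
   prior into independent 2×2 blocks per eigencomponent; each block is
   drawn exactly from its Gaussian full conditional.
3. (σ², ρ_phy): component-wise slice sampling (Neal stepping-out),
   interleaved in both the centred parameterization (g fixed) and a
   non-centred one (whitened u = chol(Σ⊗C)⁻¹ g fixed) — an
   interweaving/ASIS scheme that breaks the strong g–σ² coupling.
4. ρ_res: slice sampling.
5. Cutpoints: Gibbs from their uniform conditionals within ordering bounds.

Desk defaults: 2 chains × 2,500 iterations (800 burn-in), 10 tree draws;
`SignalConfig.paper_scale()` uses 4,000 iterations and 100 trees.
Convergence is declared when split R-hat ≤ 1.05 on λ and the two
correlations.

## Dynamic coevolution (`phylocoev.coevolution`)

The two liabilities follow a bivariate Ornstein–Uhlenbeck process along
the tree:

    dz(t) = (A z(t) + b) dt + dW(t)

with diffusion fixed to the identity (S = I) and the middle cutpoint of
each trait fixed to 0 — the two anchors that absorb the scale and location
invariance of the ordinal likelihood. The root state is drawn from the
stationary distribution N(−A⁻¹b, V∞) with A V∞ + V∞ Aᵀ + I = 0 (an option
fixes the root at the stationary mean instead). At the tips, an additive
spatial Gaussian process per trait (squared-exponential kernel on
great-circle distance, amplitude a_d, lengthscale ℓ_d) absorbs geographic
autocorrelation before the probit cut.

Branch transitions are exact: for edge length t,
M = e^{At}, m = A⁻¹(M − I) b, and vec(V) solves the Kronecker-sum system.
These are evaluated by a closed-form 2×2 eigendecomposition (complex-safe,
with triangular/diagonal special paths), compiled with numba, and
cross-checked in tests against the generic `expm`/Kronecker route to
~1e-14.

Priors: A entries N(0, 1) truncated to the stable region (eigenvalues with
negative real part); diagonal entries constrained negative. b ~ N(0, 1).
Outer cutpoints N(0, 2) within (−8, 0) and (0, 8). GP amplitude
half-normal(1), log-lengthscale flat on a wide bounded range.

Sampler (per iteration):

1. Cutpoints: partially collapsed slice updates with the liabilities
   integrated out (ordinal likelihood given the latent-state means), then
2. tip liabilities redrawn from truncated normals,
3. all node latents + whitened GP field jointly from their Gaussian full
   conditional via a sparse-structured precision matrix and Cholesky solve,
4. (A, b): adaptive-covariance random-walk MH in the centred space,
   interweaved with MH and component-wise slice steps in a non-centred
   (whitened) space,
5. GP amplitude by Gibbs (truncated normal) plus a rescaling slice move
   that trades amplitude against the whitened field; lengthscale by slice
   sampling.

Desk defaults: 2 chains × 1,600 iterations (600 burn-in), GP on, 10 tree
draws; `paper_scale()` uses 4,000 iterations and 100 trees. Convergence
threshold: split R-hat ≤ 1.01 on A, b, Δθ, cutpoints and GP amplitudes.

Reported effect: Δθ_{d←e} = −(A_de / A_dd) · MAD_e, where MAD_e is the raw
(unscaled) median absolute deviation of the posterior-mean tip liabilities
of trait e — the equilibrium shift of trait d per typical variation in
trait e. Each posterior draw of A yields a draw of Δθ; summaries are
medians, 95% HPD intervals, posterior probabilities of positivity, and a
Savage–Dickey log Bayes factor against Δθ = 0 using the analytic prior
density of Δθ at zero implied by the truncated-normal prior on A
(φ(0)·e^{1/2}/MAD_e).

`phase_plane` returns nullclines and the stationary point θ* = −A⁻¹b;
`ancestral_states` converts posterior node latents to per-level
probabilities through the cutpoints, per posterior tree.

### Recovery and calibration studies

`recovery_experiment` simulates datasets under known (A, b, cutpoints),
fits each, and reports 95%-HPDI coverage. Study condition: the spatial GP
amplitude is fixed to 0 in both generator and fit — the study isolates the
selection parameters; spatial confounding is exercised separately in the
integration tests. Null calibration simulates with A12 = A21 = 0 and
checks that the posterior probabilities of the Δθ effects stay far from
both 0 and 1.

## Multistate CTMC (`phylocoev.multistate`)

The 4-state authority-structure trait evolves by a continuous-time Markov
chain with up to 12 free rates. Five nested models are compared by zeroing
transitions: full; strong differentiation (q02 = q03 = q13 = 0); weak
differentiation (q02 = q03 = 0); strong unification (q01 = q02 = q31 = 0);
weak unification (q01 = q02 = 0). Likelihood: Felsenstein pruning with
per-node scaling and uniform (or stationary) root frequencies, compiled
with numba via a factored eigendecomposition of Q (real-spectrum fast path,
complex-safe fallback) — tested against the pure-numpy pruning and against
brute-force enumeration over internal states on small trees.

Priors: each free rate ~ Exponential(mean m), with hyperprior
m ~ Uniform(0, 10). MCMC: joint random-walk on log rates plus a reflected
walk on m. Marginal likelihoods by stepping-stone sampling with powers
β_k = (k/K)^{1/α}, α = 0.3, warm-starting each stone from the last state
of the previous one and combining with a log-sum-exp estimator. Model
comparison reports 2 ln BF with Kass–Raftery labels.

Desk defaults: 3 chains × 100,000 iterations, K = 20 stones × 3,000
iterations. `paper_scale()` restores 100 stones × 100,000 iterations and
100,000,000-iteration chains. The 3,000-iteration stones are a deliberate
desk-scale choice: with warm starts, longer stones changed desk-scale
log-ML estimates by far less than the Bayes-factor margins of interest.

## Synthetic data (`phylocoev.simulate`)

Birth–death trees (birth 1.0, death 0.3, conditioned on n tips) via
dendropy, rescaled to unit depth; uniform coordinates in a Pacific-like
box (lat −45…25, lon 95…180); liabilities simulated by exact OU
transitions from a stationary root; spatial GP noise added at the tips
before probit ordinalization; structure trait by Gillespie simulation.
Default generator: A = [[−1, 0.5], [0.4, −1]], b = 0, cutpoints ±0.85,
GP amplitude 0.3 with lengthscale 1,500 km. The generator emulates the
model classes the package fits — it does not emulate borrowing/horizontal
transmission, observation error in the codings, or non-ultrametric trees.

## MCMC infrastructure (`phylocoev.inference`)

Split R-hat (each chain halved), Geyer initial-monotone-sequence ESS,
sorted-window HPD intervals, a generic adaptive-metropolis engine
(Robbins–Monro scale plus empirical-covariance adaptation, frozen after
burn-in), a 1-D slice sampler, and a generic stepping-stone driver. The
diagnostics are cross-validated against arviz in the test suite.

## Numerical choices

- OU tip covariances get a 1e-8·(trace/n) jitter before Cholesky; the GP
  kernel gets an amplitude-scaled jitter with escalation on failure;
  log-lengthscale proposals are clipped to a wide bounded range.
- Chain seeds are derived deterministically from the user seed, chain index
  and tree index via distinct large multipliers, so runs are reproducible
  and chains independent.
- Stability of A is enforced at construction (`OUParams`) and in proposals;
  near-defective 2×2 systems (eigenvalue gap < 1e-8) are rejected rather
  than regularized.

## Known limitations

- **λ is not identified on star phylogenies.** With free ordered cutpoints
  the ordinal likelihood is exactly invariant to scaling the cutpoints by k
  while scaling the total liability variance σ² + 1 by k²; on a star tree
  (C = I) there is no tip covariance to break this, so the λ posterior is
  prior-dominated (median ≈ 0.6 regardless of truth; confirmed by an exact
  collapsed-likelihood profile and an independent collapsed sampler). On
  realistic trees the tip correlations identify λ and recovery coverage is
  nominal. Practical consequence: a λ HPD interval whose lower bound
  approaches 0 should be read as weak identification, not strong evidence
  of no signal. The acceptance suite keeps a deliberately failing test
  documenting this.
- Stepping-stone estimates at desk scale carry Monte-Carlo error of order
  0.1–0.5 log units; comparisons with |2 ln BF| < 2 should be rerun at
  `paper_scale()`.
- The coevolution model fixes S = I; drift anisotropy is absorbed into A
  and the cutpoints and is not separately estimable from ordinal data.
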