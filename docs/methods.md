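# Methods

`paramodiv` reimplements a comparative-phylogenetics workflow for a binary
habitat contrast (páramo vs non-páramo; equivalently exposed vs sheltered
microhabitat) on a posterior sample of dated trees: state-dependent
diversification, habitat/altitude regression of leaf morphology, and
state-dependent rates of continuous-trait evolution. This note records the
models, the numerical choices, and what the synthetic world does and does
not establish.

Throughout, state 0 = non-páramo/sheltered and state 1 = páramo/exposed.
Field data often score páramo *presence* as 0; the I/O layer expects the
positive coding (`paramo = 1` means present), so λ1 always reads as the
páramo speciation rate.

## BiSSE likelihood (`paramodiv.bisse`)

The binary-state speciation–extinction model assigns a lineage in state
*i* a speciation rate λᵢ, extinction rate μᵢ and anagenetic transition
rate q_ij. Along each branch, integrating rootward from the tipward end:

    dEᵢ/dt = μᵢ − (λᵢ + μᵢ + q_ij)Eᵢ + q_ij E_j + λᵢ Eᵢ²
    dDᵢ/dt = −(λᵢ + μᵢ + q_ij)Dᵢ + q_ij D_j + 2λᵢ Eᵢ Dᵢ

with tip conditions Dᵢ = fᵢ for the observed state (0 otherwise) and
Eᵢ = 1 − fᵢ, where fᵢ is the per-state sampling fraction (defaults
f1 = 22/43, f0 = 4/12 — the study's counts of sampled/described species
per habitat). At internal nodes Dᵢ ← Dᵢᴸ·Dᵢᴿ·λᵢ.

Numerics: branches are integrated child→parent in postorder by an
adaptive Cash–Karp Runge–Kutta 4(5) (rtol 1e-8, atol 1e-10) compiled with
numba; D is renormalized at every node with the log factor accumulated,
so underflow only occurs when the likelihood is genuinely 0 (returned as
−inf). E at an internal node is the mean of its children's values (they
coincide on ultrametric trees).

Root treatment: by default root state weights are the relative
magnitudes wᵢ = Dᵢ/ΣD (the behaviour of the standard reference
implementation of this model family); `equal` and `stationary`
(q-equilibrium) weightings are options. Conditioning on survival —
division by Σᵢ wᵢ λᵢ (1−Eᵢ)² — is off by default; both flags are exposed
because the original analysis does not state them.

Fitting: four parameter-sharing schemes — `full6` (λ0, λ1, μ0, μ1, q01,
q10), `eq_rates4` (λ, μ, q01, q10), `sdd_speciation4` (λ0, λ1, μ, q),
`null3` (λ, μ, q) — are optimized in log-parameter space (bounds
[1e-8, 1e3]) with L-BFGS-B from a birth–death-informed start
(λ ≈ ln(n/2)/height, μ = λ/2, q = 0.1/height) plus jittered restarts
(3 by default). Non-converged fits are flagged and excluded from
cross-tree averages. AICc uses n = number of tips — the only defensible
sample-size proxy for a tree-wide likelihood; AICc values are therefore
comparable only within this convention.

Marginal ancestral states: P(node = i) ∝ the whole-tree likelihood with
the node's state clamped to i. Rather than recomputing the full
likelihood per node (the oracle the tests use), one postorder pass stores
each branch's 2×2 linear D-propagator and a preorder pass accumulates the
root-coefficient matrices, giving all marginals in O(n) branch
integrations. The nonlinearity of the relative-D root weighting in the
clamped D is handled exactly. Branch painting assigns each edge its child
node's argmax marginal state; exact ties take the parent's assignment
(root ties state 0, both logged); pendant edges take the observed tip
state.

## PGLS with Pagel's λ (`paramodiv.pgls`)

Residual covariance σ²·V(λ), where V(λ) multiplies the off-diagonal of
the tree's shared-path-length matrix C by λ. Given λ, β̂ and the ML
σ̂² = e'V⁻¹e/n are closed-form; the λ profile is evaluated on a 0.01 grid
over [0, 1] and refined by bounded scalar search in the best bracket
(reported λ̂ matches a dense-grid brute force to 1e-4). k counts every
design column plus σ² and λ — λ's estimation consumes information, so
AICc values are comparable only within this convention. The adjusted R²
is the GLS analogue, 1 − (1−R²)(n−1)/(n−p−1), with R² computed against an
intercept-only fit under the same V.

The model set per leaf trait is altitude; habitat; altitude+habitat;
altitude×habitat (always with main effects). Responses are
natural-logged by default (configurable); altitude stays in metres;
habitat enters as a 0/1 dummy with non-páramo/sheltered as the reference
level. Trees keep one tip per sampled locality with per-locality trait
means attached; tips with missing data are dropped (and the tree pruned)
with a logged count. A perfectly collinear design or a constant response
yields a flagged degenerate fit rather than a crash.

## State-dependent Brownian motion on painted trees (`paramodiv.traitrate`)

A painting splits the BM covariance exactly: C_s(i,j) is the length of
state-s edges on the shared root→MRCA path, and C0 + C1 equals the full
covariance to machine precision (a tested invariant). The four models
share or split the mean and rate by state (k = 3, 4, 4, 5 with λ):

    V = λ-transform( σ² · (C0 + r·C1) ),   mean group = tip's observed state

with r the exposed:sheltered rate ratio (sheltered ≡ 1, bounds
[1e-6, 1e6] in log space). Transform order is deliberate: state-rate
scaling first, λ on the off-diagonals last — λ is read as a
tip-measurement-noise adjustment, which acts after the evolutionary
covariance is assembled. Mean groups follow tip observed states, not
pendant paintings (they coincide by construction of the painting). Means
and σ² are profiled in closed form; (λ, log r) are optimized by
multi-start L-BFGS-B. If a state is absent from the tips the state-mean
design degrades to a common mean, and a single-state painting fixes
r = 1, both flagged.

BM ancestral states for phylomorphospace plots are the GLS/conditional-
expectation values (root = GLS grand mean), which coincide with the joint
ML node values under BM.

## Model scoring (`paramodiv.modelselect`)

AICc = −2logL + 2k + 2k(k+1)/(n−k−1); Akaike weights
w_m = exp(−Δ_m/2)/Σexp(−Δ/2). Across a tree sample, AICc, ΔAICc and
weights are computed per tree and arithmetically averaged (averaging
weights preserves the simplex; weighting averaged ΔAICc does not — the
distinction is under test). Parameters are summarised as the median with
5th/95th percentiles across trees using the linear-interpolation quantile
rule (the default of mainstream statistics environments; percentile
reproduction depends on it). The "best model" is the lowest mean AICc;
mean weights are also printed. Failed fits are excluded with counts; a
model missing from more than half the trees is an error.

## Synthetic world (`paramodiv.simulate`)

All randomness uses the counter-based Philox generator with named
per-operation streams from one seed, so every operation is independently
reproducible bit-for-bit.

* **Trees**: exact Gillespie simulation of the binary-state birth–death
  process from a two-lineage crown (stem start optional), root state
  drawn from the q-stationary distribution by default; whole-clade or
  one-sided crown extinction is handled by rejection within a retry
  budget. With a taxon-count stop rule the tree is observed at a uniform
  time between the Nth birth and the next event — observing exactly at
  the Nth birth would leave zero-length pendant cherries whose BM
  covariance is singular at λ = 1. Event histories (births, deaths,
  transitions) are returned for balance checks.
* **Sampling**: each tip is retained independently with its state's
  fraction; defaults 22/43 and 4/12.
* **Posterior emulation**: a "posterior sample" is built from one true
  tree by a lognormal whole-tree scale factor (sd 0.1, divergence-time
  uncertainty) plus per-edge lognormal jitter (sd 0.05), re-ultrametrized
  by extending pendant edges. Topology is shared across the sample —
  real posteriors also vary topologically, so green pipeline tests
  establish score plumbing and rate recovery, not robustness to
  topological conflict.
* **Traits**: painted-BM draws come from the exact MVN implied by the
  painted covariance (single Cholesky draw). Regression data use
  altitude ~ Uniform(2800, 5000) m in páramo and Uniform(600, 3000) m
  below (the habitats' cited ranges), and a λ-transformed BM residual
  scaled so `resid_sigma2` is the tip-level variance. Default effect
  sizes: log pinna length β0 = 4, β1 = −6e-4 /m, β2 = −0.8, β3 = +3e-4
  (decline with altitude, shorter in páramo, shallower decline there);
  log leaves per frond β0 = 2.2, β1 = +3e-4, β2 = +0.9, β3 = 0 with
  residual λ = 0 — magnitudes chosen once to mirror the qualitative
  published pattern at realistic trait scales.

## Known limitations

* ML Pagel's λ is bounded in [0, 1]; at or near the boundary its mean is
  necessarily below the truth (measured ≈ 6e-4 at truth 1, n = 100), and
  at interior truths it carries the known finite-sample downward bias
  (≈ −0.04 at truth 0.7, n = 100). The optimizer is verified against a
  dense-grid oracle; the bias is the estimator's, not the optimizer's.
* E-averaging at internal nodes is exact only for ultrametric trees;
  dated chronograms are ultrametric, and inputs are checked with
  `check_ultrametric`.
* AICc's n = tips convention makes scores comparable within, not across,
  packages using other conventions.
* No hidden-state diversification models, no OU/early-burst trait
  models, no measurement-error regression models, no topological
  posterior emulation.
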