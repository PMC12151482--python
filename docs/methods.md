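# Methods

## Model and assumptions

`burstpop` models the concentration `x(t)` of a long-lived protein in a
growing, dividing cell as a piecewise-deterministic Markov process (PDMP):
deterministic flow punctuated by random jumps.

* **Bursts.** Synthesis happens in instantaneous bursts at frequency `λ`
  with exponentially distributed sizes of mean `β` (concentration units).
  Burst frequency and size are taken invariant to cell size — expression
  rates are assumed to scale with volume.  In growth-coupled mode the burst
  propensity is `λ/(1+kx)`, tying transcription to the growth rate.
* **Dilution and feedback.** Between bursts,
  `dx/dt = −γx/(1+kx) − d·x`.  `γ` (per unit time) is the maximum dilution
  rate; `k` (per concentration unit) quantifies growth inhibition by the
  protein, which acts as an effective positive feedback on concentration;
  `d` is ordinary first-order degradation (default 0: a stable protein).
  All rates are in inverse model time; nothing carries wall-clock meaning.
* **Division.** In the feedback model, division is a point process with the
  growth rate `γ/(1+kx)` as hazard, and daughters inherit the mother's
  concentration.  In the partitioning model, divisions follow an i.i.d.
  timer (gamma-distributed cycle time) or an adder size-control rule, and
  the inherited concentration jumps through the partitioning kernel below.
* **Concentration is continuous and non-negative** throughout.  There is no
  molecule-count mode, no explicit mRNA or promoter states, and no spatial
  structure, cell death or resource competition.

The two observation protocols are:

* *single-cell (lineage)*: follow one randomly chosen daughter after every
  division; statistics over many independent lineages at a fixed late time;
* *population*: keep both daughters, pool all live cells of many colonies
  at a fixed time with equal per-cell weight.

## Stationary laws

Both stationary densities have the form
`(1+kx) · C · e^{−t·x} (t·x)^{s−1}` with `(s, t) = (λ/γ, 1/β − kλ/γ)` for the
single-cell law and `(s, t) = (ξ, 1/β − kξ)`, `ξ = (λ/γ)/(kβ+1)`, for the
population law.  The implementation exploits an exact identity: each law is
a two-component gamma mixture

    p = βt · Gamma(s, 1/t)  +  βks · Gamma(s+1, 1/t),

whose weights sum to one precisely because `t = 1/β − ks`.  Moments, cdf and
exact sampling all come from the mixture; adaptive quadrature of the pdf
(`scipy.integrate.quad` on the tilted scale `u = t·x`, absolute tolerance
1e−10) is retained as an independent numerical route, and the test suite
requires the two to agree to 1e−8 relative.  This mixture algebra — rather
than any typeset moment formula — is the package's normative definition of
the moments; the weak-feedback (first order in `k`) and strong-feedback
(`k → ∞` at fixed single-cell mean) expansions are provided separately and
are checked against it.

A law exists iff its tilt rate is positive; boundary points (tilt exactly 0)
are classified as non-existent.  Requesting a non-existent law raises an
error naming the violated condition.  In the regime where only the
population law exists, lineage simulations are expected to diverge: the
simulator flags trajectories crossing a configurable cap instead of raising.

## Partitioning kernel

Daughter concentration `x⁺` must satisfy `E[x⁺|x] = x`, `Var[x⁺|x] = εx`,
support `(0, 2x)`; the complementary daughter receives `2x − x⁺`.  The
default kernel is a symmetric beta on `(0, 2x)` with shape
`a = (x/ε − 1)/2`, which matches both conditional moments exactly and is
feasible whenever `x > ε`.  For `x ≤ ε` the prescribed variance `εx ≥ x²`
is infeasible on an open `(0, 2x)` support; the kernel falls back to a
discretized binomial: `m ~ Binomial(n, ½)` with `n = max(3, round(x/ε))`
"effective molecules" and `x⁺ = 2x·m/n` (note `Var(2x·m/n) = x²/n`, so this
`n` reproduces `εx` when feasible), with boundary outcomes `m ∈ {0, n}`
rejected to keep daughters strictly positive.  The realized variance in the
fallback regime is therefore deliberately below the infeasible target — the
closest valid analogue rather than silently wrong moments.

## Cell-cycle timing and calibration

Timer cycle times are gamma-distributed, parameterized by mean and squared
CV (`cv2_tau = 0` is a point mass).  Two mean conventions exist:

* `default_cycle_mean(γ) = ln2/γ` — the volume-doubling time of a cell
  growing exponentially at rate `γ`.  This is the package's default and the
  convention under which the single-cell partitioning noise
  `(CV²)SC = (ε/(2 ln2) + β)/x̄` is exactly invariant to the cycle-time
  distribution.  An exact renewal-reward argument gives
  `(CV²)SC = ε/(2 γ⟨τd⟩ x̄) + β/x̄` for *any* cycle-time law, so invariance
  holds precisely when `⟨τd⟩` is held at `ln2/γ`.
* `calibrate_cycle_mean(cv2, γ)` — the Euler–Lotka calibration
  `⟨τd⟩ = a(2^{1/a} − 1)/γ` (`a = 1/cv2`), which instead fixes the
  *population* growth rate at `γ` (doubling time `ln2/γ`).  The two coincide
  for a deterministic timer and differ by up to a factor `1/ln2` at
  exponential cycle times; under this calibration the single-cell noise
  varies with `cv2_tau` as the formula above dictates.

The packaged partitioning experiments use the fixed-mean convention, since
it is the one under which the noise-invariance statement holds and the one a
growth-rate-`γ` dilution picture implies.

**Stationary phase.** The first cycle of every lineage root and colony
progenitor is drawn from the renewal-equilibrium residual-life distribution
(size-biased gamma times a uniform), making the division phase stationary
from `t = 0`.  This matters most for the deterministic timer: without it,
colonies stay internally synchronized at an arbitrary common phase and the
pooled variance depends on the snapshot phase (by up to ~10%).  With
residual-phase roots and snapshots at integer multiples of `⟨τd⟩`, every
colony has completed the same number of divisions, cells ages are uniform
across colonies, and the population noise equals the single-cell noise
exactly in the fixed-cycle-time limit — the behavior the fixed-`τd`
equivalence analysis predicts.  The adder root's phase is likewise
uniformized in time.

**Adder mode.** Volume grows exponentially at rate `γ` (configurable);
division fires when the volume added since birth reaches a gamma-distributed
threshold (mean `mean_added`, squared CV `cv2_added`), independent of
newborn size; volume halves at division; concentration partitions through
the `ε` kernel.  This is the minimal adder giving size homeostasis;
volume-partitioning errors are not modeled.

## Simulation algorithms

* **Lineage, feedback model** — exact event-driven scheme: exponential
  burst waiting times (in growth-coupled mode, candidates at the bound `λ`
  thinned with acceptance `1/(1+kx(t))`, exact because `λ(x) ≤ λ`); the flow
  between events is the closed-form dilution solution (principal Lambert-W
  branch for `d = 0`; for `d > 0` the conserved quantity
  `ln x + (γ/d) ln(γ+d+dkx)` is inverted with bracketed root finding).
  A fixed-step tau-leaping integrator (default `γΔt = 0.01`) is provided as
  an optional cross-check and must agree with the exact scheme within
  Monte-Carlo error.  Sampling grids always include event times; values are
  never interpolated across a jump.
* **Lineage, partitioning model** — within a cycle, either the
  deterministic relaxation `dx/dt = λβ − γx` or bursts with exponential
  decay; at division the kernel is applied and one daughter is followed
  uniformly at random.
* **Colony** — agent-based expansion from one progenitor.  Cells are
  statistically independent given their birth state, so the colony is
  expanded depth-first rather than through a global event queue — identical
  in law and simpler.  Hazard-mode divisions use the same exact thinning
  (propose at `γ`, accept with `1/(1+kx)`).  Snapshots advance every live
  cell deterministically to the exact stop time.  A per-colony cell cap
  (default 2^16) flags truncation explicitly.  Ensembles use many small
  colonies on independently spawned random streams, so colony counts never
  perturb each other.

**Ensemble protocol.** The default estimator is the endpoint ensemble —
statistics at a fixed late time across independent replicates (lineages) or
colonies — with a single-trajectory time-average mode available as an
ergodicity cross-check.  Feedback-model lineage runs either start from
`x0 = 0` with a burn-in of ~50 dilution times (relaxation time is `1/γ`) or
warm-start from the exact stationary sampler; colony runs warm-start the
progenitor from the single-cell law and run ≥ 10 dilution times, long
enough for the pooled law to relax to the population law (verified against
quadrature).

## Estimators

Mean, CV² (variance over squared mean; divisor-`n` convention, as the CV² is
a distribution property estimated from large ensembles) and skewness (third
central moment over variance^{3/2}).  Degenerate samples have CV² = skew = 0
by convention.  Standard errors are bootstrap: i.i.d. resampling for lineage
ensembles, whole-colony resampling for pooled population statistics
(respecting within-colony dependence).  Perspective comparisons report
population/single-cell ratios with delta-method error propagation and a
significance flag at two propagated SEs.  Distribution agreement uses the
Kolmogorov–Smirnov sup-distance against the mixture cdf.

## Problem sizes and defaults

The packaged experiments follow the study protocol — 5000 lineages, 2000
colonies, 6 generations, `γ = ln2` time units for the partitioning studies —
with a `--fast` mode at one tenth scale.  The test suite exercises the same
checks at reduced replicate counts (hundreds of colonies, thousands of
lineages), with every stochastic assertion stated as a ±3-standard-error
band computed from the data, so reduced counts widen tolerances rather than
weaken the check.  The acceptance script uses the full protocol sizes.

## What the synthetic ensembles do and do not show

All inputs are generated by the model itself; there is no external data.
Passing tests therefore demonstrate internal consistency — simulators agree
with the exact stationary laws, closed forms agree with quadrature, both
perspectives behave as the theory predicts across feedback, partitioning,
degradation, growth-coupling, timer and adder regimes — not that the model
describes any particular organism.  Real single-cell data bring features the
model abstracts away: cell-size-dependent expression, mRNA and promoter
dynamics, extrinsic parameter fluctuations, correlated sister-cell cycle
times beyond the adder, and measurement noise.

## Known limitations

* Time-dependent (transient) distributions are not computed analytically;
  only stationary laws plus simulation.
* The population growth prefactor is reported as a fitted exponential rate;
  no eigen-expansion of the population balance equation is attempted.
* For `x ≤ ε` the partition kernel cannot realize variance `εx` (see above).
* Closed-form moments for the growth-coupled and degradation variants are
  not provided; those regimes are studied by simulation against limiting
  laws (e.g. the gamma law when degradation dominates dilution).
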