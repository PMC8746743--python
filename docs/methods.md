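# Methods

## Decision model and conventions

Trial-level behaviour is a two-boundary drift-diffusion process: evidence
`x(t)` starts at `a/2` (no response bias), drifts at rate `v` toward the
correct boundary `a`, with diffusion coefficient `σ`, and the response time
adds a non-decision time `ndt`.  The closed forms used throughout,

`ER = 1/(1 + exp(a v/σ²))` and `DT = (a/2v)·tanh(a v/2σ²)`,

are the standard expressions for error rate and mean decision time of an
unbiased diffusion, re-expressed in the boundary-separation convention
(start at `a/2`) so that "threshold" means the same quantity in the
normative predictions and in fits.  For `|v| < 10⁻⁶` the analytic limits
`ER = 1/2`, `DT = a²/4σ²` (and the matching derivative limits) replace the
0/0 expressions.

`σ` is fixed at 1 and treated as a unit convention, not a free parameter:
the diffusion model is identified only up to a scaling of `(v, a, σ)`, so
drift rates and thresholds are reported in σ-units.  It is configurable but
constant across conditions.

## The objective

`RR(v, a) = [R(1−ER) − P·ER]/(DT + ndt) − E·cost(v)`

* `R > 0`, `P ≥ 0` — subjective value of a correct response and (positive)
  magnitude of the penalty for an error, in effort-cost units.
* `E ≥ 0` — effort-cost weight, default 1.  Optima depend only on `R/E`
  and `P/E`, so normalising `E = 1` loses no generality.
* `cost(v)` — `v²` (default), `|v|`, or `exp(v) − 1`; the exponential form
  is anchored so the cost vanishes at `v = 0`, which is a modelling choice
  of this package (only the family, not the offset, is standard).
* Threshold carries no effort cost by default: raising `a` already pays an
  implicit price through slower responding.  A quadratic threshold-cost
  hook (`CostSpec.threshold_weight`) exists and defaults to 0.
* `ndt` defaults to 0.4 s for normative predictions.

Without a drift cost the objective is unbounded in `v`; the optimizer
refuses to run in that configuration rather than returning a boundary
artefact.

## Optimization

`optimize_policy` is deterministic: a 200×200 log-spaced coarse grid over
`v ∈ [10⁻³, 50]`, `a ∈ [10⁻², 20]` locates the basin; L-BFGS-B with the
analytic gradient refines it; a Newton polish (root solve of the two
stationarity equations) drives the gradient to machine precision when the
optimum is interior.  The returned policy records the residual gradient
norm and is marked non-converged — never silently accepted — if it fails
the first-order check (‖∇RR‖∞ < 10⁻⁵ × objective scale), lands on the
search boundary, or fails to beat the coarse grid.  The smooth,
single-peaked landscape this relies on is verified against a dense-grid
argmax oracle in the tests rather than assumed.

## Inversion

At fixed `(v, a)` both partial derivatives of `RR` are affine in `(R, P)`,
so the stationarity conditions form a 2×2 linear system

`A(v, a, ndt) · (R, P)ᵀ = b(v, ndt, cost)`

solved directly (`b` carries the cost derivative; with a threshold cost its
second entry becomes nonzero).  The solve is rejected with an explicit
error when the condition number exceeds 10¹⁰; negative solutions — observed
configurations no positive incentive pair can rationalise — are returned
with a validity flag, never clipped.  The linear route is verified against
a nonlinear root-finder on the same equations, and `invert ∘ optimize` is
the identity to 10⁻⁴ relative tolerance on interior optima.  Boundary-
pinned optima have no stationary point and are excluded from that identity
by construction.

## First-passage sampler

Trials are simulated by Euler–Maruyama with a 1 ms step.  Plain
Euler–Maruyama absorbs late (the path can cross and return within a step),
biasing `DT` upward by ~0.58·σ√dt per boundary, which is detectable at the
sample sizes used here.  Each step therefore applies a Brownian-bridge
crossing check: given interior endpoints `x₀ → x₁`, the path still crossed
the upper boundary with probability `exp(−2(a−x₀)(a−x₁)/σ²dt)` (lower
boundary analogous), and a uniform draw decides absorption.  This removes
the leading-order discretisation bias, making the 1 ms sampler
indistinguishable from the exact distribution at 10⁵-path resolution (the
double-crossing probability it neglects is `O(exp(−2a²/σ²dt))`, negligible
for `a ≥ 0.1`).  Crossing times within the final step are recorded at
mid-step.  Paths unabsorbed after 120 s (practically impossible for sane
parameters) are scored by their current side.  Seeds are explicit
everywhere; batch draws use the jitted kernel's own seeded stream.

## Estimation

`estimate_ddm` is a deterministic moment estimator in the EZ style: from
accuracy and the mean and variance of correct-trial RTs it inverts the
closed-form moment equations for `(v, a)` and recovers `ndt` as
`mean RT − mean DT`, with `σ` fixed.  Accuracies of exactly 0, 1, or 0.5
make the inversion undefined and raise a coded `EstimationError` rather
than returning a silent number.  An optional maximum-likelihood polish
(`refine=True`, used by default in the recovery pipeline) maximises the
Wiener first-passage likelihood — an image-series density whose truncation
is chosen adaptively so the neglected tail is below `exp(−40)` — via
Nelder-Mead from the moment start.  The refinement uses error-trial RTs
and the full RT shape, which matters most where errors are rare.
Hierarchical/Bayesian fitting is deliberately out of scope; the moment+ML
estimator is desk-scale, deterministic, and sufficient for the recovery
results the package reports.

## Recovery simulation

`run_recovery` validates the chain optimize → simulate → estimate →
invert on a grid of ground-truth weights.  Defaults, chosen once:

* 5×5 log-spaced grid, `R ∈ [8, 20]`, `P ∈ [5, 125]`.  The reward range
  matches the span over which the normative optima are tabulated.  The
  penalty ceiling is set by estimability, decided from the closed form
  before any recovery run: at `P = 125` the error rate at the optimal
  policy is ~0.007 (≥ ~13 expected errors in 2000 trials), whereas by
  `P = 625` it falls to ~0.001 and a 2000-trial cell routinely contains no
  errors at all, leaving the moment equations undefined.
* 2000 trials per cell in the `fitted` regime; a `noiseless` regime
  (invert the exact optimum) is also provided since it is not documented
  which regime the original validation used.
* Inversion uses each cell's estimated `(v, a)` with the shared
  session-level `ndt` rather than the cell's own ndt estimate, matching
  per-condition estimation with a shared non-decision time.
* Cells failing estimation or inversion are reported per-cell;
  correlations are computed only when ≥ 90% of cells succeed.

Recovered-vs-true Pearson correlations are ~0.99 for `R` and ~0.93–0.99
for `P` across seeds; penalty recovery is reliably the harder of the two
because high-penalty optima have very low error rates, so the error-rate
estimate that anchors the inversion rests on few observed errors.

## Task generator

The generator emulates the incentivized Stroop paradigm: fixed intervals
drawn uniformly from 8–12 s; as many self-paced trials as fit, a new trial
starting immediately after each response; cued per-interval reward/penalty
levels (2×2 of {1¢, 10¢} with 20 intervals per condition, or 3×3 of
{1¢, 5¢, 10¢} with 8); congruence i.i.d. Bernoulli(0.5), so the realised
congruent fraction varies slightly across intervals; earnings tracked
exactly as `reward·n_correct − penalty·n_error`.

Per-condition parameters come from `build_profile`: the congruent-trial
`(v, a)` is the reward-rate optimum for that condition's subjective
weights; incongruent trials apply a drift decrement and threshold
increment (defaults 0.3 and 0.1 σ-units) — interference demands control,
and the profile invariant rejects any "facilitation" configuration.

The default mapping from cued cents to subjective weights is linear with a
baseline: `R = 8 + 1.2·cents`, `P = 10 + 3·cents`.  The baseline encodes
that even 1¢ trials are performed with high accuracy; the steeper penalty
slope encodes the usual loss-aversion asymmetry (equal cents weigh more as
losses).  These defaults yield accuracy ~0.92–0.97 and correct-trial RTs
~0.53–0.75 s — session-plausible behaviour — and were fixed before any
end-to-end test was run.

A trial still in flight when the interval ends is discarded by default;
the alternative `truncate_as_omission` policy records it with no outcome.
How such trials were actually scored in the original task is not
documented, so both options exist and neither is asserted as canonical.
Block structure (one incentive fixed per block, the other varying) is
recorded as metadata only — the analyses implemented here model no order
effects.

**What the generator does not emulate:** between-subject parameter
heterogeneity beyond the weight scheme, sequential effects
(post-error slowing, congruence sequence effects), within-interval
fatigue or learning, RT contamination (lapses, fast guesses), and any
reward×penalty×congruence interaction unless injected through
per-condition offsets.  Passing end-to-end tests therefore show that the
estimation/inversion machinery recovers the generative structure it
assumes — not that real Stroop data satisfy that structure.

## Pipeline and reproducibility

A run is fully specified by a `RunConfig` plus one seed; the master seed
fans out through `numpy.random.SeedSequence` into per-subject and
per-stage streams, so stages can be re-run in isolation and re-running a
config overwrites byte-identical outputs.  Every artefact directory
carries a manifest with the config hash and seed.  Outputs are plain
CSV/JSON throughout.

## Problem sizes

Default analyses are sized for a single workstation core: recovery uses a
25-cell grid at 2000 trials/cell (a few seconds); Monte-Carlo validation
of the closed forms uses 10⁵ paths per parameter point; synthetic cohorts
of 4–8 subjects give ~1200–2500 trials per condition, comfortably above
the 100-trial floor the estimator enforces.

## Known limitations

* The inversion presumes the observed `(v, a)` is an interior optimum of
  the stated objective; behaviour that is not reward-rate-optimal under a
  quadratic drift cost yields flagged (possibly negative) weights rather
  than a model-comparison verdict.
* The linear cost's kink at `v = 0` excludes gradient-based machinery
  there; the optimizer handles it away from zero only.
* Moment-based estimation ignores RT contamination and across-trial
  parameter variability (sv, sz, st are out of scope), so on real data the
  recovered weights inherit any misfit of the plain DDM.
* Recovery quality degrades intrinsically as incentives push error rates
  toward 0; this is an identifiability property of the design, not an
  implementation ceiling.
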