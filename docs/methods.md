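# Methods

## Model

`rtfit` fits the retarded transient function (RTF) — sustained component
`A(1−e^{−αt})`, transient component `B(1−e^{−βt})e^{−γt}`, offset `b` — on a
retarded time axis `t(t_real, τ) = log10(10^(10 t_real/T) + 10^τ) −
log10(1 + 10^τ)`. The division by the time range `T` makes the
transformation unit-free; `T` is computed once per dataset as
`max(time) − min(time)` pooled over all doses, conditions and replicates,
so all curves share one transformed axis. The model targets non-oscillatory
responses with at most one peak; oscillations or multi-peak dynamics are
outside its validity and are not handled.

Dose dependence replaces each dynamic parameter `{A, B, α, β, γ, τ}` by a
Hill law `M d^h/(K^h + d^h)`; `τ` uses the decreasing form
`M (1 − d^h/(K^h + d^h))` since delays shrink with dose. Condition
differences are multiplicative fold-changes Δ > 0 applied scalar-wise
(each `M`, `K`, `h`, optionally `b`) to the reference condition's values.
The error model is additive Gaussian with one shared σ across all doses,
conditions and replicates; replicates enter the likelihood as independent
observations. Grouped or relative error models are deliberately not
implemented (single-σ is the reference implementation; the `ParameterSpace`
abstraction is the extension point).

### The K = 0 convention

`K = 0` is a *structural flag* meaning "no dose dependence": the Hill law is
then defined as the constant `M` for **both** directions and all doses,
including `d = 0`. This makes the single-dose RTF the exact sub-model with
all `K = 0` (parameter values equal to the `M`s) and makes eliminating a
dose dependence (`K → 0`) collapse the triplet to its `M`. Note this is a
definition, not a limit: the decreasing form tends to 0 pointwise as
`K → 0+` at fixed `d > 0`, so the map `K ↦ H(d; K)` is discontinuous at 0.
During optimization `K` is always strictly positive (its bounds derive from
the dose ladder); `K = 0` arises only through model structure, never as an
estimate.

### Parameter accounting

Dose-dependent dynamic parameters contribute `{M, K, h}`; dose-independent
ones a single scalar; plus `b` and σ; plus one Δ per condition-dependent
scalar and non-reference condition. Fixing `B = 0` removes the transient
part together with `β` and `γ` (they lose all influence); fixing `A = 0`
removes `α`. A tie (`γ ≡ α` by default in the convenience constructors,
reflecting that sustained and transient parts are usually triggered
together) removes the tied parameter's scalars and is applied *after* Hill
evaluation, so a tied rate tracks its source at every dose. The raw
`ModelSpec` dataclass applies no tie by default so that the canonical
tie-free structures (20-parameter full model, 8-parameter plain RTF) are
the literal defaults of the constructor arguments.

## Estimation

Gaussian maximum likelihood over all points. Data-driven default bounds:

| parameter | lower | upper | initial | scale |
|---|---|---|---|---|
| `M_A`, `M_B` (up-regulation) | 0 | `2(max y − min y)` | `0.1·lb + 0.9·ub` | linear |
| `M_A`, `M_B` (down-regulation) | `−2(max y − min y)` | 0 | `0.9·lb + 0.1·ub` | linear |
| `M_α`, `M_β`, `M_γ` | `1/(2(max t − min t))` | `2/min gap between times` | midpoint | log10 |
| `M_τ` | `−(max t − min t)/5` | `(max t − min t)/2` | `−(max t − min t)/10` | linear |
| `h` | 1 | 10 | midpoint | log10 |
| `K` | `min(dose>0)/10` | `max(dose)·10` | midpoint | log10 |
| `b` | `min y` | `max y` | midpoint | linear |
| σ | `min(ub, max(1e−10, (max y−min y)/1e4))` | `max(1e−10, SD(y))` | midpoint | log10 |
| Δ | 1e−2 | 1e2 | 1 | log10 |

`y` is restricted to reference-condition responses when several conditions
are present (the reference defines the scale); times and doses are pooled.
Time-derived bounds use the raw measurement times (unique, sorted); the
smallest gap between distinct time points sets the fastest resolvable rate.
The Δ bounds span two orders of magnitude — generous for biological
fold-changes — with neutral initial guess 1. Strictly positive parameters
(rates, `K`, `h`, σ, Δ) are optimized and profiled on log10 scale; signed
ones (`M_A`, `M_B`, `M_τ`, `b`) on linear scale. Down-regulation is
expressed by sign-flipping the amplitude bounds; `K` and `h` stay positive.

Optimization is multi-start: the data-driven initial guess first, then
Latin-hypercube draws on the optimization scale, each refined with bounded
L-BFGS-B (finite-difference gradients, `ftol` 1e−11, up to 500 iterations).
`n_starts` defaults to 50 for exploratory fits; the simulation studies use
6–20 starts, which the waterfall diagnostic (sorted final objectives) shows
to reach the best optimum repeatedly at those problem sizes. A fit is
flagged `converged_repeatedly` when ≥ 2 starts agree within 1e−3. The
elimination and type-I studies additionally warm-start refits from the
current optimum and repair the rare multi-start miss where a nested model
out-scores its supermodel.

## Uncertainty

Profiles step away from the MLE on the parameter's optimization scale,
re-optimizing all other parameters at each step (warm-started from the
neighbouring step, with a fallback restart from the MLE). The step size
adapts towards ~0.1 log-likelihood units per accepted step; steps
overshooting fourfold are retracted and refined, up to 100 accepted steps
and 400 re-optimizations per direction. Scanning stops once the profile
falls `χ²₁(level)/2 + 0.5` below the optimum or a bound is hit; a side that
never crosses the threshold is reported open at the bound. CI endpoints
interpolate linearly between grid points and are reported on linear scale.
The threshold is the pointwise χ²(1 df) quantile (1.9207 in LL units at
95%); simultaneous intervals are out of scope. A fold-change is significant
when Δ = 1 (log Δ = 0) lies outside its profile CI — the same decision as a
level-α LRT of the shared-parameter model; a CI open on both sides flags the
Δ as unidentifiable and never significant.

## Model reduction

Backward elimination treats two kinds of term: a Hill dose-dependence
(collapse to the constant `M`, dropping `K` and `h`, LRT with 2 df) and a
condition fold-change (fix Δ = 1, 1 df per non-reference condition). Each
round refits every candidate removal (warm start + 10 fresh LHS starts) and
permanently removes the one with the *largest* p-value if it exceeds α
(default 0.05), stopping otherwise. Greedy ordering can matter in
principle, so the trail records every tentative LRT for audit; an
exhaustive-order search is out of scope. Terms marked protected (prior
knowledge) are never candidates.

## Synthetic data

The generator draws `value = RTF(time, dose; condition) + N(0, σ²)` with a
fixed seed. The shipped fixture emulates a nigericin-dose inflammasome
activation ELISA design: 7 log-spaced doses (1–10 µM-like), 8 time points
over 6 h-like units, 3 replicates, sustained-only responses (`B = 0`), and
a wild-type reference with Hill laws on `A` (M=1, K=3, h=2), `α` (M=1.2,
K=2, h=2) and `τ` (M=1.5, K=4.5, h=4), offset 0.05. σ is defined as exactly
2% of the noise-free surface range (≈0.0183). The truth was chosen once so
that every Hill law has its EC50 inside the dose ladder and approaches both
plateaus within it — the signature of a well-designed dose-finding
experiment and a prerequisite for the `M` and `K` parameters to be
identifiable at all; in particular the delay's EC50 sits *above* the
amplitude's, so the delay plateau overlaps doses with measurable response.
The knockout-like condition applies fold-changes Δ on
`{A_M: 0.4, alpha_M: 0.5, tau_M: 1.6, A_K: 1.8, alpha_h: 1.8}` — a blunted,
slowed, delayed response with shifted and steepened dose dependence.

What the fixture does *not* emulate: dose-dependent or multiplicative error,
plate effects, missing wells, outliers, or left-censoring at the assay's
detection limit. Passing recovery tests on it therefore demonstrates the
estimator's correctness under its own assumptions, not robustness to those
real-data complications.

## Validation studies and their sizes

The `benchmarks` module regenerates all inputs and measures, per run:
parameter accounting (20 / 11 / 35 / 8); the K = 0 degeneracy (20 random
parameter sets × 13 times × 6 doses, machine precision); parameter recovery
(20 simulated experiments of the fixture design; median relative errors —
`A_M` ≈ 0.5%, `α_M` ≈ 3%, `τ_M` ≈ 8–9%, `A_K` ≈ 1%; the delay maximum is
the hardest because only low doses, where the response is smallest, inform
it); profile-CI agreement with the analytic Gaussian interval on a
48-point constant-response toy (≤ 1e−4); fold-change power (Δ_{A_M} = 2
detected) and type-I error (3 null Δs × 20 seeds; 0–3 false rejections per
Δ is within binomial fluctuation of a calibrated 5% test); backward
elimination recovering a dose-independent delay (10 seeds); and the
joint-vs-individual single-dose comparison, scored as χ² with σ fixed from
the joint fit (10 vs 28 fitted parameters on the 7-dose design; LRT
p-value far above 0.05, i.e. the Hill structure loses nothing). These sizes
were chosen so the full battery completes in minutes on one CPU while
keeping the Monte-Carlo error of each summary far below its decision
margin.

## Degenerate inputs and numerics

The time transform is computed in log-sum-exp form and survives exponents
far beyond float range. Hill fractions use `1/(1 + (K/d)^h)` with the
`d = 0` limit taken explicitly (0 for increasing, `M` for decreasing laws
with `K > 0`). Datasets need ≥ 3 distinct time points, a positive response
range, and ≥ 2 distinct doses (with at least one positive) for any
dose-dependent structure; violations raise typed errors before any
optimization. At dose 0 with `K > 0` every rate evaluates to 0 and the
response degenerates to the offset — rates of exactly 0 are therefore
admitted as boundary values of the parameter container, while negative
rates and σ ≤ 0 are rejected.

## Known limitations

- Single additive σ only; heteroscedastic assays must be pre-transformed.
- Profiles are pointwise, not simultaneous; no prediction profiles and no
  bootstrap/Bayesian alternatives.
- Greedy elimination can be order-dependent (the trail exposes this);
  no AIC/BIC or forward selection.
- The delay maximum `M_τ` is intrinsically weakly identified when low
  doses produce little response; expect wide CIs there in real data.
- Analytic gradients are not implemented; fits rely on finite differences.
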