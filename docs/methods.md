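# Methods

## The epidemic block

The compartment recursion is the deterministic mean-field SIRD model with a
vaccination flow from S straight to R. Shares are real numbers, not counts;
conservation S+I+R+D = 1 is exact by construction (every flow appears once as
an outflow and once as an inflow). Parameters are constant over time.
Feasibility demands γ+ρ ≤ 1 and τ_t + δI_t ≤ 1 so that the individual
transition kernel is row-stochastic; the package fails fast with the
violated constraint and period rather than clipping. At the exact feasibility
boundary (τ_t + δI_t = 1) the complement entry can underflow to −ε in
floating point and is clamped to zero. Vaccination and infection are treated
as simultaneous competing outflows from S within a period; schedules shorter
than the horizon repeat their last value (logged once per trajectory).

State ordering is (S, I, R, D) in every array, CSV and kernel in the package.

## Consumption and utility

Equilibrium is no-trade with symmetric holdings k (default 1): every living
individual consumes b_t + d_t·k + w(θ), the deceased consume 0. This is the
consumption rule implied by unstorable endowments when the cross-sectional
distribution of holdings is degenerate, and it is the regime in which the
pricing display below is valid (the "almost everyone is susceptible"
approximation).

Utility must satisfy u(0) = 0, u′ > 0, u″ < 0. Two families are provided:

- power, u(c) = c^(1−σ)/(1−σ) with σ ∈ (0,1), default σ = 0.5. Log utility is
  excluded because u(0) is undefined; σ ≥ 1 is excluded for the same reason.
  u′(0) = ∞, so this family cannot price the deceased.
- bounded exponential, u(c) = 1 − e^(−αc), α > 0. u′(0) = α is finite, which
  is what the deceased-inclusive pricing convention requires.

The `infected_excluded` variant pins c(I) at a fixed floor (default
10⁻³·w_S) that does not respond to handouts, modelling infected individuals
shut out of economic activity while keeping marginal utility finite.

## The pricing series and its truncation

For an individual susceptible at t,

m = Σ_{ω≥1} β^ω d_{t+ω} Σ_θ P(θ at t+ω | S at t) · weight(θ) · u′(c_{t+ω}(θ)),

with the state distribution pushed forward through the per-period kernels
(Chapman–Kolmogorov). The price is p̃_t = m / u′(c_t(S)).

weight(θ) = 1 for living θ. For the deceased the package implements two
conventions and treats the choice as a genuine modelling fork:

- `exclude_deceased` (default): weight(D) = 0. This matches the series as
  displayed (sums over {S, I, R} only) and is interpretable as the tree being
  destroyed at death (k_{t+1}(D) = 0). Probability mass is genuinely lost, so
  m depends on ρ.
- `include_deceased`: weight(D) = 1 with u′(0) finite (bounded exponential
  only). No mass is lost; death is the worst consumption state.

Truncation: the series is cut at the first horizon Ω with
β^(Ω+1)/(1−β) · sup d · sup u′ < tol (default tol = 1e−10, max_horizon 2000),
where sup u′ is evaluated at the smallest consumption any weighted state can
attain over the schedules. The bound is certified (every omitted term is
dominated) and recorded on the result; a `ConvergenceError` carrying the
achieved bound is raised if max_horizon is hit first. On the baseline preset
Ω = 474.

## The sign of dp̃/dτ and why one acceptance check is red

The derivative of m in τ_t decomposes as Σ_ω Δ_{t+ω} with

Δ_{t+ω} = β^ω d_{t+ω} ( E[weight·u′ | enter R at t+1] − E[weight·u′ | stay S at t+1] ).

Δ_{t+1} = 0 exactly since c(S) = c(R). Under the default exclude-deceased
convention the comparison term is

Δ_{t+ω} ∝ P_D(ω)·u′(c_S) − P_I(ω)·(u′(c_I) − u′(c_S)),

where P_I, P_D are the infected/deceased probabilities of the S-branch
individual. The infection term is transient (an infection spell lasts
1/(γ+ρ) periods in expectation); the mortality term accumulates, because a
dead individual is removed from the pricing weight forever while the
R-branch keeps full weight. Hence Δ is negative at short horizons (on the
baseline: ω = 2..14) and positive afterwards. Whether the total is negative
is a horse race between ρ/(γ+ρ)·1/(1−β) (death) and 1/(γ+ρ) (infection);
with the pinned calibration (γ=0.2, ρ=0.05, β=0.95) both equal 4.0 and the
death term wins on marginal utilities, so dp̃/dτ is a small positive number
(+5.1e−4 partial mode) and handouts amplify rather than attenuate it. The
three acceptance tests asserting the negative-sign claims on this preset are
therefore red by design; they are kept at face value rather than weakened.

Under `include_deceased` the comparison adds P_D·(u′(c_S) − u′(0)) < 0, every
Δ_{t+ω} (ω ≥ 2) is negative at any horizon, and all the headline results
hold: dp̃/dτ < 0, |dp̃/dτ| shrinking in the handout, and the reversal under
`infected_excluded`. The test suite asserts all of these for the
deceased-inclusive kernel.

Two results are convention-independent and exact: the zero-gap/no-mortality
knife edge (all living states consume alike and no mass dies, so m is
invariant to δ, τ, γ and dp̃/dτ = 0 to machine precision) and the δ = 0
symmetry (vaccination only swaps S for R at equal consumption).

## Differentiation modes

`partial` (default): only the period-t kernel's τ is perturbed; the aggregate
trajectory and all later kernels are held fixed. This is the object the
analytic decomposition differentiates, and because m is affine in the
first-step τ the central difference is exact up to truncation — the suite
checks dp̃/dτ = (ΣΔ)/u′(c_t(S)) to the tail tolerance. `full`: the whole
trajectory is re-simulated with τ_{t_eval} perturbed, letting vaccination
feed back into future infection risk; this is the economically complete
derivative. Central differences use h = 1e−4 by default with a one-sided
fallback (logged) at the feasibility boundary; a Richardson ratio test in
full mode confirms O(h²) error decay.

## Oracles

Two independent routes check the deterministic distribution recursion:

- exhaustive enumeration of all 4^ω health-state paths (coded separately in
  the test suite from the primitive q formulas, with its own consumption and
  marginal-utility arithmetic) — agreement to 1e−12 at horizons ≤ 6;
- a seeded Monte-Carlo path sampler (10⁵ paths, inverse-CDF draws per
  period) — agreement within 3 standard errors at the full truncation
  horizon. A single seed (default 20220421) drives all sampling.

## What the presets do and do not establish

The presets are a stated world, not a calibration to data: the theory under
study is qualitative and supplies no numbers, so the baseline pins a
mid-sized epidemic (2% initially infected, 5% per-period vaccination), a
large income gap (w_I/w_S = 0.2) and standard discounting (β = 0.95). Green
tests establish internal consistency of the pricing recursion, its analytic
decomposition and the comparative statics *under the stated conventions*;
they do not establish that real asset prices respond to vaccination with any
particular sign or magnitude, nor anything about time-varying epidemic
parameters, trading dynamics, heterogeneous holdings, or general-equilibrium
price determination away from the mostly-susceptible approximation.

## Numerical conventions

Tolerances: conservation and oracle equivalence at 1e−12; closed-form price
at 1e−10; knife-edge derivative at 1e−8 (finite-difference noise floor);
sweep monotonicity uses strict inequalities with 1e−12 slack. Kernel rows are
built as complements; row sums are checked to 1e−15 (1 ulp). CSV output is
full-precision, `.` decimal, UTF-8, LF. Reports are JSON with sorted keys so
identical runs are byte-identical.
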