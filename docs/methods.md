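# Methods

This note documents the models implemented in `stdpsync`, their
assumptions, the numerical choices made where the mathematics leaves room,
and what the synthetic protocols do and do not capture about real spike
trains.

## Doublet STDP and the lag-distribution picture

The pair-based (doublet) rule assigns each *relevant* presynaptic/
postsynaptic spike pair with synapse-site lag `Δt = t_post − t_pre − d` a
weight change

    F(Δt) = A+ · exp(−Δt/τ+)   for Δt > 0,
    F(Δt) = −A− · exp(Δt/τ−)   for Δt < 0,

with all times in milliseconds.  `d = d_ax − d_bap` is the *effective*
transmission delay: axonal conduction delay minus the dendritic delay of
the back-propagating action potential.  Soma-synchronous spikes therefore
arrive at the synapse with lag `−d`, which is why positive delays push
synchronized firing toward depression.

`F(0)` is mathematically undefined in the rule above; `stdpsync` defines
`doublet_kernel(0) = 0`.  Simultaneous arrival at the synapse carries no
causal information, exact ties have probability zero under the continuous
protocols, and the neutral value biases neither branch.

If lags follow a density `G`, the expected change per pairing is
`Δw = ∫ F(t) G(t) dt`.  For a rectangular `G` of height `c` on `[t1, t2]`
this integral is elementary, with three cases (window entirely positive,
entirely negative, straddling zero); mixtures of rectangles add by
linearity.  A synchronization event of width `T` with delay `d` gives the
uniform window `c = 1/T` on `[−T/2 − d, T/2 − d]`, and the three cases
become delay regimes: `d < −T/2` (pure LTP), `d > T/2` (pure LTD),
`|d| ≤ T/2` (mixed).  The implementation evaluates the piecewise
closed form directly; a redundant second route (window construction +
per-piece integration) and an adaptive-quadrature oracle
(`scipy.integrate.quad` of `F·G`) guard it in the tests, at tolerances
1e−12 and 1e−8 respectively.  These tolerances are implementation
decisions; the underlying agreement is at rounding level (~1e−17).

Two shape facts matter for interpretation and are asserted as tests:

* For the realistic kernel (`A+ = 0.0147, A− = 0.0073, τ+ = 13 ms,
  τ− = 34 ms`) at fixed positive delay there is a single interior optimum
  of `Δw` over `T` (≈17 ms at `d = 1` ms on our grid): coarse
  synchronization maximizes coupling; both very precise synchronization
  and the flat-lag limit (`T·Δw → ∫F = A+τ+ − A−τ− < 0`) depress.
* For the near-symmetric kernel (`A+ = 1.1·A−`, `τ+ = τ−`) the LTD region
  dominates all small-to-moderate windows at positive delay, and within it
  depression weakens monotonically as the window coarsens.  Two
  second-order caveats that contour plots do not resolve: `Δw` turns
  weakly positive at very large `T` and then decays like
  `(A+−A−)·τ/T` (a shallow maximum, under 5% of the depression depth),
  and inside the pure-LTD zone `T < 2d` the depression deepens *slightly*
  (O(T²/τ²)) as `T` grows.  The tests state the claims in the form that is
  actually true of the closed form: the sign along `T` flips at most once,
  and the mixed-branch LTD is monotone.

## Weight-dependent doublet rules and equilibrium weights

Two standard weight dependences are implemented on top of the same lag
picture:

* **Power law**: `A+ = η·w0^{1−μ}·w^μ`, `A− = η·α·w` (potentiation
  sub-linear in the weight, depression linear).  Setting the expected
  change to zero for `|d| ≤ T/2` gives

      w∞/w0 = ( τ+(1−e^{−(T/2−d)/τ+}) / (α·τ−(1−e^{−(T/2+d)/τ−})) )^{1/(1−μ)} ,

  which in the rate-coding limit `T → ∞` (or for `d = 0`, `τ+ = τ−` at any
  `T`) reduces to `(τ+/(α·τ−))^{1/(1−μ)}` — ≈ 39.6 for the original
  parameters (μ = 0.4, w0 = 1 pA, η = 0.1, α = 0.11, τ± = 20 ms).  For
  `d > T/2` the weight decays to zero; for `d < −T/2` the rule predicts
  unbounded supra-linear growth.  The latter is returned as a tagged
  sentinel (`regime="unbounded_ltp"`, value NaN) rather than infinity so
  that sweeps can render the region distinctly; the `T → ∞` limit is an
  explicit analytic mode rather than a large-`T` evaluation, avoiding
  cancellation in the exponentials.
* **Interpolating rule**: `A+ = η(1−w)^μ`, `A− = η·α·w^μ`, weights confined
  to [0, 1]; `μ → 0` approaches the additive rule, `μ = 1` is
  multiplicative.  The equilibrium is a logistic in the same branch ratio
  with exponent `1/μ`; it is evaluated in log space because `ratio^{1/μ}`
  overflows for the almost-additive preset (μ = 0.001) long before the
  weight leaves [0, 1].

The "adapted" power-law preset matches the realistic doublet kernel at the
reference weight: `η·w0 = 0.0147` and `α = 0.0073/0.0147`, with
`τ+ = 13 ms, τ− = 34 ms`.  (One published figure caption states this α as
`0.0073/0.00147`, which is inconsistent with the stated pair amplitudes and
is treated here as a dropped-digit typo; any α can still be set explicitly
via config overrides.)  The interpolating presets use `η = 0.0147` so the
additive limit reproduces the same kernel.

## Nearest-neighbor triplet STDP

The triplet rule adds a dependence on the previous same-side interspike
interval: at each postsynaptic spike the weight grows by
`s·e^{−Δt1/τ+}(A2+ + A3+·e^{−Δt2/τy})`, where `Δt1` is the time since the
last presynaptic spike and `Δt2` the time since the previous postsynaptic
spike; at each presynaptic spike it shrinks by
`s·e^{−Δt1/τ−}(A2− + A3−·e^{−Δt2/τx})` with the roles reversed.  "Last" and
"previous" are strict predecessors at the synapse site; a spike with no
opposite-side predecessor produces no update, and a missing same-side
predecessor only zeroes the triplet gate.  The global factor `s` scales all
four amplitudes (default 1).  With `A3± = 0` the rule reduces exactly to
nearest-neighbor doublet STDP.  The shipped fits are the minimal
hippocampal set (`A2+ = 0.0046, A3+ = 0.0091, A2− = 0.003, A3− = 0,
τx = 575, τy = 48, τ+ = 16.8, τ− = 33.7` ms) and the minimal visual-cortex
set (`A2+ = 0, A3+ = 0.05, A2− = 0.008, A3− = 0, τx = 714, τy = 40,
τ+ = 16.8, τ− = 33.7` ms).

For a regular oscillatory protocol in which both neurons fire exactly once
per period `1/f`, the postsynaptic neuron without jitter at `i/f` and the
presynaptic spikes uniform within `±T/2`, the expected change per cycle has
a closed form.  The postsynaptic interspike interval is constantly `1/f`,
so the potentiation gate is the constant prefactor
`A2+ + A3+·e^{−1/(f·τy)}` and only the `Δt1` distributions need
integrating; they are uniform mixtures with the same three delay regimes
as the doublet analysis (same-cycle versus previous-cycle partners in the
mixed regime).  The depression term requires `A3− = 0`, which the minimal
fits satisfy; the analysis rejects parameters violating it.  Note a wording
slip in the source derivation: the depression expression is introduced as
an "expected potentiation" but carries the prefactor `−A2−`; it is
depression, and is implemented as such.

Validity requires `T ≤ 1/f` and `|d| < 1/f − T/2`; grid cells violating
this are masked, not errored.  A consequence worth knowing: with the
visual-cortex fit (`A2+ = 0`) the potentiation prefactor at 5 Hz is
`0.05·e^{−5} ≈ 3.4e−4`, far below `A2− = 0.008`, so no `(T, d)` cell with
positive delay can potentiate — under one-spike-per-cycle stimulation,
LTP at low rates requires bursting (small `Δt2`), which this protocol
excludes by construction.

The central correctness evidence is Monte-Carlo: the event-driven
nearest-neighbor simulator run on the generated one-spike-per-cycle
protocol must agree with the closed form within three standard errors,
over random `(f, T, d)` tuples for both fits.  Two estimator details: the
first two cycles are discarded as burn-in so every spike has well-defined
partners, and the standard error uses batch means over 10-cycle blocks
because per-cycle changes of adjacent cycles share spike partners and are
positively autocorrelated (~0.12 at lag 1), which a naive per-cycle
standard error underestimates by about 10%.

One bookkeeping subtlety: "nearest-neighbor doublet" is defined
pre-centrically (each presynaptic spike pairs with its nearest preceding
and nearest following postsynaptic spike), while the triplet rule with
`A3± = 0` pairs via last-partner lookups.  On the one-spike-per-cycle
protocol the two differ only through previous/next-cycle terms suppressed
like `e^{−(1/f − T/2 − |d|)/τ}`; the cross-validation of the doublet
reduction is therefore run at 5 Hz, where the difference is orders of
magnitude below the Monte-Carlo resolution.

## Synthetic stimulation protocols

The generator implements a two-state Poissonian firing model on a discrete
grid of step `dt = 0.1 ms` (at most one spike per neuron per step, spike
probability `λ(t)·dt`):

* **Oscillatory**: stimulation events of width `T` recur with frequency
  `f`; the in-event rate derives from the target mean rate by
  `λ1 = λ/(fT) − λ0(1/(fT) − 1)` so the mean rate is met exactly.
* **Non-oscillatory**: an event starts at every step with probability
  `λe·dt`; overlapping events do not stack the rate.  The probability that
  a step lies outside all events is `p0 = (1 − λe·dt)^{T/dt}` and
  `λ1 = (λ − p0·λ0)/(1 − p0)`.
* **Rate**: homogeneous firing at the mean rate.

Defaults follow the study conditions throughout: background rate
`λ0 = 1 spike/s`, `dt = 0.1 ms`, synchronization windows of 1–10 ms for
the precise/coarse contrast, mean rates of a few spikes/s for the
low-activity regime, and burst ratio `λ/λe = 2` in the non-oscillatory
example configs.  Event times are shared between the two neurons; the
per-step spike draws are independent per neuron.  Parameters implying
`λ1 < 0` or `λ1·dt ≥ 1` are rejected with the offending value reported.
The root seed is split into sub-streams for event placement and for each
neuron, so regenerating with a longer duration does not reshuffle early
events.  Delays are never baked into stored trains — trains are
soma-referenced and the delay enters only at lag computation — matching
the convention of the closed forms.

What the generator does *not* emulate: refractory periods (the two-state
Poisson model allows spikes in adjacent 0.1 ms steps), bursting structure
beyond what the elevated in-event rate induces, phase jitter of the
oscillation itself, and any rate adaptation.  Tests passing on these
protocols therefore demonstrate correctness of the plasticity accounting
and of the closed forms *under the stated firing model*, not robustness of
the biological conclusions to refractoriness or non-stationary rates.

The one-spike-per-cycle generator is separate and deterministic in
structure (postsynaptic spikes exactly at `i/f`, starting at cycle 1 so
every recorded spike time is positive); it exists as the Monte-Carlo
counterpart of the triplet closed form.

## Pairing semantics and simulators

All-to-all pairing collects every pair within `max_lag` (default 200 ms,
about six depression time constants of the realistic kernel; beyond it
kernel contributions are below 0.3% of the amplitude).  Nearest-neighbor
pairing collects, per presynaptic spike, the nearest strictly preceding
and the nearest following postsynaptic spike, with "nearest" judged at the
synapse site (after the delay shift).  Boundary spikes keep only the
partners that exist — no wrap-around, no phantom pairs.  Exact ties are
processed post-before-pre and contribute nothing (zero-lag kernel value,
strict triplet predecessors).

Weight trajectories apply pair contributions in chronological order of
each pair's later spike.  For the linear kernel the total is
order-independent (a pure sum, asserted against an order-shuffled sum) and
is evaluated vectorized; with a weight-dependent rule the amplitudes are
recomputed from the current weight before every update, sequentially.
Interpolating-rule weights are clipped to [0, 1] by default; arbitrary
clip bounds are applied after each update when given.

Monte-Carlo surfaces report the mean weight change *per postsynaptic
spike* (matching the normalization of the published contour figures) with
per-cell standard errors over independent protocol realizations, and a
three-standard-error rule classifies cells as coupling, decoupling or
indeterminate.

## Problem sizes

The shipped tests and the acceptance script size their simulations to
seconds of runtime while keeping the statistics conclusive: 100-second
protocol realizations for rate checks, 4×10⁴-cycle simulations in module
tests and 10⁵-cycle simulations in the acceptance checks of the triplet
closed form, 30–100 random parameter triples for the quadrature oracle,
and 50×50 grids for phase-structure assertions.  All are stated choices of
this package, reproducible via the fixed seeds in the tests and the
`--seed` argument of the acceptance script.

## Known limitations

* The closed forms cover rectangular lag mixtures only; empirical lag
  distributions from the Poissonian protocols are handled numerically by
  the simulators, not analytically.
* The triplet closed form exists only for the idealized one-spike-per-cycle
  protocol with `A3− = 0`; jittered or multi-spike protocols are simulated,
  not solved.
* The all-to-all triplet variant and network-level simulations (recurrent
  circuits, inhibition, habituation) are outside the package's scope.
* Absolute magnitudes of published contour plots depend on normalization
  conventions that are not fully specified; the package anchors on signs,
  monotonicity, equilibria and the quadrature/Monte-Carlo oracles instead.
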