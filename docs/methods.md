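# Methods

## Model overview

`homeorate` simulates homeostatic control of a single neuron's firing
rate. The neuron is a firing-rate unit

    tau_r dr/dt = -r + F[g_E S_E(t) + g_I S_I(t) - T],
    F[X] = r_max / (1 + exp(-X / sigma)),

with tau_r = 10 ms, r_max = 100 Hz and sigmoid width sigma = 20 input
units throughout. S_E(t) is a piecewise-constant synaptic drive; the
inhibitory term g_I S_I is implemented but defaults to zero (none of
the shipped experiments exercises it). Two slow variables are under
homeostatic control: the threshold T (intrinsic excitability) and the
excitatory conductance g_E (synaptic scaling). Because T is subtracted
from the input while g_E multiplies it, T shifts only the mean of the
rate distribution whereas g_E also scales its spread — which is why
every stable dual configuration assigns the higher/more-curved
set-point to the conductance controller.

A controller here never pins the instantaneous rate; it pins a
*statistic* of the rate distribution sampled over many input
fluctuations. All controllers are therefore run slow relative to the
input switching (see time-scale choices below).

### Controllers

* **Integral feedback** (`integral_feedback_derivative`,
  `conductance_homeostasis_derivative`): feedback accumulates the
  error, so the only fixed point is the set-point.
* **Dual linear–quadratic** (`quadlin_derivatives`):
  `tau_T dT/dt = r - r_goal_T`, `tau_g dg/dt = r_goal_g^2 - r^2`. At
  stationarity the time-averaged drives vanish, pinning `<r> =
  r_goal_T` and `<r^2> = r_goal_g^2`, hence `Var(r) = r_goal_g^2 -
  r_goal_T^2`. Feasibility requires `r_goal_g > r_goal_T`; the shipped
  demonstrations use 10 and 15 Hz (variance set-point 125 Hz²).
* **Generalized two-function control** (`generalized_derivatives`):
  arbitrary monotone `f_T`, `f_g`. Stability without fine-tuning
  requires the function with the larger curvature index `f''/f'` at
  its target to drive the conductance (`check_curvature_condition`).
* **Dual bang–bang** (`bangbang_derivatives`): Heaviside drives with
  `H(0) = 1`; each controller enforces a target fraction of time the
  rate spends at or above its step-point. Cooperation requires
  `r_step_g > r_step_T` and `p_T > p_g` (demonstrations: step-points
  1 and 15 Hz, fractions 0.5 and 0.1). Because a stationary
  integrator's drive time-averages to zero, the achieved fraction
  equals its target exactly in the long run, independent of the taus.

### Wind-up

When the two set-points cannot be satisfied by any rate distribution,
each controller ratchets its feedback indefinitely ("wind-up").
`detect_windup` flags a variable when its two trailing windows (each
one third of the final input regime, so that legitimate
regime-boundary transits are not counted) show same-signed linear
drifts each exceeding 10% of the variable's mean absolute level, or
when the variable passes a hard bound (500 by default in the
experiment runners — one to two orders of magnitude beyond any
functioning operating point of these models). The thresholds are
diagnostic choices of this package; wind-up in the underlying models
is a qualitative phenomenon.

With the physical floor g_E >= 0 active, the flipped linear–quadratic
configuration does not diverge: the conductance collapses to zero and
the neuron goes silent with T stabilized — a degenerate, equally
non-homeostatic end state reported as `g_pinned_at_zero`. The wind-up
demonstration (`fig3b`) therefore lifts the floor to let the
instability escape to non-physiological (negative-conductance) levels,
which the bound criterion flags on both variables.

### Biochemical cascade

The pathway r → C → K → {m_g → g, m_T → T} uses one stage template
`tau dx/dt = -D(x) + f(upstream)`. Calcium removal is linear
(`dC/dt = -C/tau_C + r`), so C is a low-pass filtered copy of the
rate. Degradation laws (`DegradationSpec`) are linear, Hill-saturating
(`V_max P^n / (K_half^n + P^n)`, zeroth-order once `P >> K_half`), or
ideally constant. A constant-degradation stage does not settle at a
level dictated by its input — it integrates its input and is the
controller's memory. `mode="dual"` places constant degradation at the
two expression stages (D_g, D_T); `mode="single"` places it at the
kinase stage (D_K), making g and T two co-regulated outputs of one
controller.

Default forward maps:

* `f_K(C) = f_K_max C^n / (f_K_max/k_f + C^n)` — Hill-saturating with
  low-calcium asymptote `k_f C^n`; `n_K = 3` by default (calmodulin-
  like supralinearity; a quartic is also plausible but an early fit of
  kinase activation against calcium suggested an exponent near three),
  `k_f = 10`, ceiling `f_K_max = 400`. The ceiling is biologically
  necessary (full activation exists) and numerically essential: an
  unsaturated cube of a rate that can transiently hit r_max produces
  kinase spikes three orders of magnitude above the operating point,
  and those heavy tails break the moment-based control.
* `f_mT(K) = K` and `f_mg(K) = max(500 - 0.25 K^2, 0)`; `f_g(m) = m`,
  `f_T(m) = m`.

With linear mRNA filtering these choices make the dual mode's
set-points exact and interpretable: stationarity of the T-integrator
gives `<K> = D_T` and of the g-integrator `<K^2> = (500 - D_g)/0.25 =
D_g` for the shipped gains, i.e. the printed degradation rates
D_g = 400, D_T = 18 are literally the first and second moments of
kinase activation, `Var(K) = 400 - 324 = 76`, and positivity of that
variance is the feasibility constraint `D_g >= D_T^2` validated at
construction. Saturating-Hill degradation remains available for every
filter stage; the polynomial forward maps were preferred over
saturating ones precisely because they make these set-points explicit.

Filtering is the reason the kinase nonlinearity matters. Each stage
attenuates fluctuations: a first-order filter driven by broadband
noise has stationary variance proportional to 1/tau, so a 100-fold
slower stage passes 10-fold smaller standard deviations
(`variance_transfer_ratio`; the paired filters are advanced with the
exact AR(1) recursion, vectorized with `scipy.signal.lfilter`, which
is identical to the forward-Euler update). The cubic kinase step
triples relative fluctuations and keeps `Var(K) = 76` attainable; with
a linear kinase step (`n_K = 1`) the attainable kinase variance falls
short at the same D_g, D_T, the two integrators disagree permanently,
and the system winds up — threshold climbing steadily and conductance
creeping to its biophysical maximum (`g_max`, 10 in the `fig7a`
fixture), where it pins (`g_pinned_at_max`).

The single-vs-dual discriminator reported by `simulate_cascade`
classifies kinase activation as *tracking* (per-regime post-transient
means within 25% of the first regime's baseline — the dual signature,
K is only a filter of the controlled rate) or *integrating* (spread
beyond 50% — the single signature, K stores the compensation). The
25%/50% band is a classification choice of this package, sized from
the observed ~2% tracking spread and ~3-fold integrating spread.

### Information transfer

The stepped-level protocol presents n equally spaced synaptic levels
(default 10 in [0, 1]), switching every 500 ms in seeded random order;
the readout is the dimensionless noisy logistic rate
`r = 1/(1 + exp(T - I)) + eta`, `I = gain * x(t)`, with eta drawn
independently per 1-ms step (sd 0.1, unscaled by dt — it is readout
noise, not a diffusion term). Mutual information between level labels
and epoch-mean responses uses the plug-in estimator on a joint count
table with 10 equal-width response bins and no bias correction; epoch
counts are made large (1000) instead. The four illustrative operating
points (A saturated, B low-gain, C bimodal, D tuned) are package
choices matching their qualitative descriptions; only the ordering
D > A, B, C is asserted, not surface values.

## Synthetic inputs

Regime schedules hold one Gaussian draw per switch interval. The
default stress-test envelope uses four regimes with means (10, 40, 4,
20) and sds (4, 10, 2, 6): a 10-fold range of mean input and 25-fold
range of input variance. Means and sds are paired to keep the ratio
mean/sd similar across regimes, which keeps the equilibrium threshold
within a moderate band and lets desk-scale runs converge in every
regime; the envelope extremes are unchanged by the pairing. Inputs
are currents and may be negative; an optional floor exists but is off
by default.

What the generator does *not* emulate: temporal correlations within a
regime beyond the hold interval, conductance-based synaptic kinetics,
spiking variability, and multi-neuron correlations. Passing tests
demonstrate the control-theoretic behaviour of the rate model under
this idealized drive, not quantitative biology.

## Numerical choices

* Forward Euler, fixed step, dt = 1 ms everywhere (validated against
  dt <= tau_fastest/10 at setup; halving dt moves reported epoch
  statistics by < 2%, which is the convergence criterion used in place
  of an unknown reference step). No adaptive stepping: stochastic
  forcing stays well defined and runs are bit-reproducible.
* States with physical signs (rates, concentrations, conductance) are
  floored at 0 after each step; T is unbounded unless a cap is
  requested.
* Divergence guard: any non-finite state aborts with the step index
  and variable name.
* Controller time constants in the shipped demonstrations are reduced
  relative to the slow biological values (tens of minutes to hours);
  the fixed points of the integral laws are independent of the taus,
  so only a clear separation from the input timescale matters. The
  choices (e.g. tau_T = 2 s, tau_g = 8 s over 50-ms switching for the
  linear–quadratic demo; 0.5/0.25 s for bang–bang; 20/200 s expression
  stages in the cascade) keep 20–400x separation while converging
  within a few hundred simulated seconds per regime.
* Problem sizes: regime demonstrations run 4 regimes of 100–500 s at
  1 kHz stepping (0.4–2.0 x 10^6 Euler steps); the filtering analyses
  use 2 x 10^7 (tests) to 4 x 10^7 (headline recomputation) steps,
  streamed in chunks; statistics discard the first half of each
  regime as transient.
* Curvature indices use analytic derivatives when supplied, else
  central differences with relative step 1e-4.
* Epoch variance is the population (divide-by-n) variance; samples per
  epoch are in the thousands.

## Known limitations

* The cascade's unprinted kinetic constants (stage taus, gains,
  Hill constants) are this package's defaults; conclusions are
  qualitative (tracking vs integrating, wind-up vs recovery), and the
  quantitative fixed points are meaningful only relative to these
  defaults.
* The bang–bang fraction estimates carry a small (< 1%) upward bias
  from the Euler-discretized limit cycle at the lower step-point.
* Wind-up detection is heuristic; pathological slow drifts just below
  the 10%-per-window threshold would be missed.
* The MI estimator is the uncorrected plug-in; with the shipped epoch
  counts its bias (~bins x levels / 2N nats) is ~0.05 nats, far below
  the asserted orderings.
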