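# homeorate

Simulation of single and dual homeostatic controllers of neural
firing rate.

Neurons keep their firing statistics in a useful range by slowly
adjusting intrinsic excitability (the firing threshold *T*) and
synaptic strength (the excitatory conductance *g*<sub>E</sub>) in
response to their own activity. A single integral controller can pin
one statistic — typically the mean rate — but a neuron that should
*transmit information* also needs to control how much its rate
varies, and that takes two controllers watching the same spike train.
Two controllers, however, can fight: if their set-points cannot be
satisfied simultaneously, each ratchets its feedback without bound
("wind-up").

This package is a simulation toolkit for exploring when dual control
cooperates and when it fails, built around a sigmoidal rate neuron

&nbsp;&nbsp;&nbsp;&nbsp;τ<sub>r</sub> dr/dt = −r + F[g<sub>E</sub>S<sub>E</sub>(t) − T],
&nbsp;&nbsp;F[X] = r<sub>max</sub> / (1 + e<sup>−X/σ</sup>)

driven by piecewise-constant noisy input currents whose mean and
variance jump between regimes. It implements:

* **integral feedback** — the canonical single controller;
* **dual linear–quadratic control** — τ<sub>T</sub> dT/dt = r − r<sub>goal(T)</sub>,
  τ<sub>g</sub> dg<sub>E</sub>/dt = r²<sub>goal(g)</sub> − r², which pins ⟨r⟩ and ⟨r²⟩ and
  hence Var(r) = r²<sub>goal(g)</sub> − r²<sub>goal(T)</sub> (feasible only for
  r<sub>goal(g)</sub> > r<sub>goal(T)</sub>);
* **generalized two-function control** with the curvature-based
  stability rule (the more curved control function must drive the
  conductance);
* **dual bang–bang control** — Heaviside drives enforcing target
  fractions of time above two step-points;
* a six-variable **biochemical cascade** (calcium → kinase → two mRNA
  species → conductance/threshold) in which the temporal integrator is
  a zeroth-order (substrate-independent) degradation step, placeable
  at the expression stages (dual controller) or the kinase stage
  (single controller with two co-regulated outputs);
* **metrics**: plug-in mutual information (nats) between stepped input
  levels and epoch-mean responses, time-fraction statistics,
  input–output correlation, and a wind-up detector.

See `docs/methods.md` for the full model account, parameter defaults
and numerical choices.

## Worked example

Run the functioning dual linear–quadratic system (goal rates 10 and
15 Hz) across four input regimes spanning a 10-fold range of mean and
a 25-fold range of variance:

```bash
homeorate fixtures fig3a --outdir runs
homeorate simulate --config runs/fig3a.yaml --outdir runs/fig3a
```

The summary it prints (abridged):

```json
{
  "experiment": "quadlin",
  "feasible": true,
  "fixed_point_variance": 125.0,
  "curvature_condition_ok": true,
  "regime_rate_mean": [9.83, 9.99, 9.85, 9.86],
  "regime_rate_rms":  [14.91, 14.99, 14.97, 14.92],
  "regime_rate_var":  [125.8, 125.0, 127.1, 125.3],
  "windup": {"g_E": false, "T": false}
}
```

Despite the input distribution changing four times, the post-transient
mean rate returns to the 10 Hz threshold-controller target and the RMS
rate to the 15 Hz conductance-controller target in every regime; the
achieved variance matches the implied set-point
15² − 10² = 125 Hz², and neither feedback variable winds up. Swapping
the two targets (`fig3b`) makes the variance set-point negative: no
fixed point exists, `feasible` is false, and both g<sub>E</sub> and
*T* are flagged by the wind-up detector.

Other shipped fixtures: `fig4a`/`fig4b` (bang–bang, cooperative and
wound-up), `fig6a`/`fig6b` (cascade with dual vs single integration
placement — kinase activation *tracks* the rate in the dual system
but *integrates* it in the single one), `fig7a` (linear-kinase
cascade wind-up), `fig2-sweep` (mutual information across four
gain/threshold operating points), `filter100` (the square-root
filtering law). `homeorate fixtures` lists them.

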