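# ripplenet

Modeling hippocampal ripple oscillations (140–220 Hz) with an
inhibition-first spiking network and its Gaussian-drift mean-field
theory.

Sharp wave–ripples are brief high-frequency oscillation events in
hippocampal population activity. In the inhibition-first picture they
are generated by a recurrently connected interneuron network (e.g.
PV⁺ basket cells) acting as a delayed negative-feedback loop: a
transient excitatory drive from CA3 makes the population spike, the
spike returns one synaptic delay Δ later as strong inhibition, and the
loop repeats at ripple frequency. A hallmark of measured ripples is
**intra-ripple frequency accommodation (IFA)**: the instantaneous
oscillation frequency drifts downward over the event even when the
driving input is time-symmetric.

`ripplenet` implements this model end to end, for computational
neuroscientists who want to simulate it, and for theorists who want
its closed-form reductions:

* **Spiking network** — N fully connected noisy leaky integrate-and-fire
  units, `τ_m dV_i = (I_E(t) − V_i) dt + √(2 D τ_m) dW_i` minus
  delayed inhibitory pulses of size K/N (dimensionless voltage: rest
  at 0, threshold at V_T = 1). Euler–Maruyama integration, population
  rate r_N(t), Gaussian-smoothed rates, average-cycle extraction.
* **Ripple metrics** — network frequency from the rate PSD, unit
  rate/ISI statistics, saturation s = f_unit/f_net, the full-synchrony
  point, two instantaneous-frequency estimators (wavelet spectrogram
  and inverse peak-to-peak distances), and the IFA slope
  χ_IFA = Cov(f̂, t̂)/Var(t̂) pooled over repeated stimuli.
* **Gaussian-drift mean field** — the membrane-potential density is
  approximated as a Gaussian of fixed variance D whose mean μ obeys a
  delay differential equation; the population rate is the drift
  current across threshold, `r = [μ̇]₊ 𝒩(V_T; μ, D)`, optionally with
  a phenomenological population reset μ → μ_max − (V_T − V_R)·s at the
  end of each population spike.
* **Closed-form constant-drive theory** — μ_max, μ_min, saturation,
  upstroke time t_off = τ_m ln[(I_E−μ_min)/(I_E−μ_max)] and
  f_net = 1/(t_off + Δ); the full-synchrony drive; the applicability
  range; theory-vs-simulation performance scores.
* **Transient theory for ramping drive** — a per-cycle map
  (Î_E, μ_min, m) → (f_inst, μ_max, μ_reset, μ_min′) with a Lambert-W
  upstroke time, chained self-consistently over a symmetric double-ramp
  stimulus. The hysteresis of μ_min across cycles makes rising-ramp
  cycles fast and falling-ramp cycles slow — the mechanism of IFA,
  with speed-dependent slope χ_IFA(m).
* **Linear stability** — stationary state from the LIF f-I curve
  (Siegert integral) and the Hopf bifurcation of the asynchronous
  state via the exact LIF susceptibility (complex-order parabolic
  cylinder functions): critical drive, onset frequency and unit rate.

## Worked example

```python
import ripplenet as rn
from ripplenet.params import DimensionlessParams

p = DimensionlessParams()          # V_T=1, V_R=0, K=5, D=0.04, τ=10 ms, Δ=1.2 ms

# closed-form ripple cycle at constant drive I_E = 3.6
sol = rn.constant_drive_solution(3.6, p, with_reset=True)
print(f"f_net = {sol.f_net:.1f} Hz, saturation = {sol.s:.2f}")
# f_net = 235.8 Hz, saturation = 0.32

# Hopf bifurcation of the mean-field network
hp = rn.hopf_point(p)
print(f"I_ext^crit = {hp.I_ext_crit_nA:.2f} nA, "
      f"f_net = {hp.f_net_hz:.0f} Hz, f_unit = {hp.f_unit_hz:.0f} Hz")
# I_ext^crit = 0.19 nA, f_net = 305 Hz, f_unit = 16 Hz

# theoretical IFA slope for a double ramp of slope ±0.4/ms
ifa = rn.theory_ifa(0.4, p, plateau=8.9)
print(f"chi_IFA = {ifa.chi_ifa:.2f} Hz/ms")
# chi_IFA = -2.55 Hz/ms
```

The first block evaluates one asymptotic oscillation cycle: at drive
3.6 the population oscillates at 235.8 Hz while only ~32% of units
fire per cycle (sparse synchrony). The second locates the onset of
collective oscillation of the stationary state. The third chains
transient cycles over a sharp-wave-like double ramp; the negative
slope is IFA.

A thin CLI mirrors the library:

```bash
ripplenet theory --out sweep.txt          # constant-drive sweep table
ripplenet dde --drive 3.6 --out traj.txt  # DDE trajectory + regime label
ripplenet ifa-theory -m 0.4 --out chain.txt
ripplenet stability
ripplenet ifa -m 0.4 --n-runs 50 --out points.txt   # spiking-network IFA
```

## Layout

| module                  | contents                                        |
|-------------------------|-------------------------------------------------|
| `ripplenet.params`      | physical/dimensionless parameter sets, conversion |
| `ripplenet.drive`       | piecewise-linear drive profiles, SPW double ramp |
| `ripplenet.network`     | spiking simulator, rates, average cycle          |
| `ripplenet.metrics`     | f_net, saturation, instantaneous frequency, χ_IFA |
| `ripplenet.dde`         | Gaussian-drift DDE, regimes, bifurcation         |
| `ripplenet.theory`      | closed-form constant-drive cycle theory          |
| `ripplenet.transient`   | linear-drive cycle map, chaining, theory χ_IFA   |
| `ripplenet.stability`   | f-I curve, susceptibility, Hopf point            |
| `ripplenet.cli`         | command-line entry points                        |

See `docs/methods.md` for the model description, numerical choices and
known limitations.
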