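# Methods

## Model

The network is a homogeneous, fully connected population of N
leaky integrate-and-fire interneurons with instantaneous
threshold-and-reset and no absolute refractory period. In
dimensionless voltage (rest at 0, spike threshold at V_T = 1, voltage
measured in units of the rest-to-threshold distance) each unit obeys

    τ_m dV_i = (I_E(t) − V_i) dt + √(2 D τ_m) dW_i − (K/N) Σ δ-pulses,

where every spike in the population is broadcast to all N units
(self-connection included) and arrives exactly one synaptic delay Δ
later as a voltage decrement K/N. The default parameter set
(physical: τ_m = 10 ms, C = 100 pF, E_leak = V_reset = −65 mV,
V_thr = −52 mV, J = 65 mV, Δ = 1.2 ms, σ_V = 2.62 mV, N = 10⁴;
dimensionless: V_R = 0, K = 5, D = 0.04) places the network in the
ripple-generating regime. The conversion stores the exact
D = (σ_V/(V_thr−E_leak))² ≈ 0.0406 when converting physical
parameters; the dimensionless default object carries the conventional
rounded 0.04 so that closed-form evaluations reproduce the model's
standard worked numbers.

Drive is a piecewise-linear profile. The canonical sharp-wave
stimulus is a symmetric double ramp: baseline at half the critical
drive held 200 ms, linear rise at +m per ms to a plateau, 20 ms
plateau, and fall at −m. The plateau level defaults to the
*simulation-calibrated* full-synchrony drive (≈ 8.9 dimensionless for
the defaults), not to the closed-form full-synchrony expression, which
deliberately overestimates it.

## Spiking simulation

Euler–Maruyama with dt = 0.01 ms by default; per step the
deterministic drift and any delayed inhibitory kick are applied,
then the noise increment √(2 D dt/τ_m)·ξ, then the threshold test: a
unit at or above V_T emits one spike timestamped at that step and is
reset within the same step (no crossing-time interpolation, no
overshoot carry-over). Delayed arrivals use a ring buffer of per-step
population spike counts. Initial voltages are uniform on [V_R, V_T];
constant-drive analyses discard the first 50 ms. All randomness flows
from one seeded NumPy generator whose seed is recorded in the result.
The choice to apply kicks before the same-step threshold test is a
convention; halving/doubling dt changes the network frequency by
under 2%, which bounds the sensitivity to it.

The empirical population rate is the per-bin spike count divided by
N·dt (spikes/s). For display and peak detection it is smoothed with a
normalized Gaussian window of σ_t = 0.3 ms truncated at ±5σ. The
average oscillation cycle is extracted by segmenting the run at the
phase of the analytic signal (Hilbert transform) of the
population-mean membrane potential and averaging rate, voltage
histogram and mean voltage in 21 equally spaced phase bins.

## Ripple metrics

* Asymptotic network frequency: dominant peak of the Welch PSD of the
  population rate (DC excluded); flagged invalid when the peak does
  not exceed five times the median in-band power.
* Unit statistics: mean unit rate, and the coefficient of variation
  of inter-spike intervals computed per unit and averaged over units
  with at least two intervals. Saturation s = f_unit/f_net; the
  full-synchrony point interpolates the saturation curve to 1.
* Instantaneous frequency, continuous: complex-Morlet wavelet
  spectrogram (`cmor1.5-1.0`, 70–350 Hz band); per time step the
  argmax-power frequency, valid where the power exceeds the baseline
  mean + 4 SD. The wavelet parameters resolve a 100 ms, 200 Hz burst
  with well under 10 ms of time smearing (a 250→150 Hz linear chirp is
  recovered to < 5%).
* Instantaneous frequency, discrete: inverse peak-to-peak distances
  of the smoothed rate; peaks must exceed the baseline mean rate
  + 4 SD. Each frequency is stamped at the midpoint of its peak pair,
  the only convention symmetric under time reversal. A minimum peak
  separation of 2.5 ms (the 400 Hz upper edge of the analysis band)
  suppresses split-peak artifacts, and detection is restricted to the
  stimulation epoch: in small networks the baseline itself produces
  occasional super-threshold fluctuation peaks whose pairings are not
  ripple cycles.
* IFA slope: ordinary least squares of pooled valid (t̂, f̂) points,
  χ_IFA = Cov(f̂, t̂)/Var(t̂), by default over 50 independent stimulus
  repetitions (unweighted; spectral power is carried as metadata but
  not used as a regression weight).

## Gaussian-drift reduction

Between population spikes the bulk of the membrane-potential density
is far subthreshold, where the threshold boundary condition is
irrelevant and the density relaxes to a Gaussian of variance D. The
mean-field dynamics then closes on the mean μ(t):

    τ_m μ̇ = I_E(t) − τ_m K r(t−Δ) − μ,     r = [μ̇]₊ 𝒩(V_T; μ, D).

This delay differential equation is integrated by forward Euler
(dt = 0.005 ms; Δ stored as an integer number of steps) from a
constant subthreshold history. Four regimes occur as constant drive
increases: stable fixed point (μ, r) = (I_E, 0); "pathological" fast
oscillation at ≈ 1/(2Δ), an artifact of clipping the rate at zero;
period-2; and the period-1 regime the theory targets. The regime
classifier uses a rate-amplitude floor of 1e-4, an alternate-peak
height ratio of 1.05 for period-2, and a μ_min subthreshold test for
the pathological label; near-boundary cases are flagged rather than
guessed. The fixed-point/oscillation transition is located by
bisection to 1e-3.

The phenomenological population reset mimics the single-unit resets:
at the end of each population spike (μ̇ crossing zero from above after
a rate excursion) μ drops instantaneously to
μ_reset = μ_max − (V_T − V_R)·s, where s is the suprathreshold
Gaussian mass. Immediately after the reset [μ̇]₊ becomes briefly
positive again, so the rate is additionally clipped to zero for
exactly one delay after each reset; the dynamics are insensitive to
the precise window (none/Δ/trajectory-based all agree to < 0.1% in
period), but a reset must not re-trigger inside its own clip window.

## Constant-drive closed forms

Assuming (i) the population spike lasts at most 2Δ, so feedback is
negligible earlier in the upstroke, and (ii) the upstroke relaxes
exponentially towards the external drive alone, the cycle quantities
follow in closed form: μ_max from the end-of-spike condition
(independent of the cycle's starting point), μ_min by integrating the
delayed feedback over the Δ-long downstroke (erf expressions; the
with-reset variant only replaces the initial condition μ_max by
μ_reset), t_off = τ_m ln[(I_E−μ_min)/(I_E−μ_max)], and
f_net = 1/(t_off + Δ), f_unit = s·f_net. Oscillations require
K ≥ √(2πD) e^{−Δ/τ_m} and I_E above
V_T − √(2 D ln[K e^{Δ/τ_m}/√(2πD)]) (≈ 0.56 at defaults; the
numerically integrated DDE loses its fixed point slightly later,
≈ 0.62).

A transcription subtlety: the printed μ_min expression is not the
exact integral of one single history approximation — its first erf
bracket is the exact integral under a linearized upstroke history,
while its Gaussian-product bracket stems from the exponential history
with the exponentials linearized inside the integral. Both brackets
are verified against quadrature oracles at their own approximation
level, and the assembled cycle reproduces the standard worked values
(290.7 Hz without and 235.8 Hz with reset at I_E = 3.6) to 0.5 Hz.

The theory applies where units spike at most once per cycle
(I_E ≤ I_E^full, with I_E^full from μ_max − 3√D = V_T in closed form)
and the cycle minimum is sufficiently subthreshold
(μ_min + 3√D ≤ V_T, with the with-reset μ_min — this reproduces the
expected lower bound ≈ 2.85 at defaults, which the no-reset variant
does not). Root finding uses bisection to 1e-4. Against the
numerically integrated with-reset DDE over 20 drives in this range the
closed-form frequency deviates by 3% on average (1.7–2.5% over the
upper three quarters, up to ~7% at the lowest drives, adjacent to the
DDE's period-2 regime).

## Transient theory and IFA

For drive changing linearly with slope m, each cycle is anchored at
the end of its population spike (reference drive Î_E). μ_max solves a
transcendental condition (root-bracketed around the constant-drive
value, with an exact first-order perturbative fallback). The upstroke
time has a Lambert-W closed form whose physical root lies on the
principal branch for m > 0 but on the −1 branch for m < 0 (each is
the unique branch continuous with the m → 0 limit); because the
closed form cancels catastrophically for small |m|, the same equation
is solved directly by bracketed root finding when |m| τ_m ≤ 0.5, and
the two routes are cross-checked. The end-of-cycle potential μ_min′
integrates the total current over the downstroke with the Gaussian
factors evaluated on the transient upstroke trajectory; it is
computed as the constant-drive closed form plus the difference of two
quadratures (transient minus m = 0), so the m → 0 limit is exact by
construction. A literal small-m decomposition of this integral —
drift factors expanded to first order and Gaussian factors frozen at
their m = 0 history — captures almost none of the true slope
dependence (single-cycle DDE oracle: shifts of ∓0.3 in μ_min′ at
m = ±0.4/ms versus ~0.04 for the frozen-density form), which is why
the density factors follow the transient trajectory.

Cycles chain self-consistently: the drive at the end of one cycle
equals the drive at the start of the next, solved per cycle by fixed
point iteration (tolerance 1e-6 ms). The rising chain starts at the
subthreshold-validity boundary μ_min = V_T − 3√D and is anchored so
its last cycle ends exactly at the plateau drive; among anchored
chains the longest branch is chosen (the ripple starts as early as the
theory permits), located by bisection at the branch boundary of a
0.02-resolution scan. The falling chain starts from the asymptotic
plateau state and continues while cycle starts remain subthreshold
and the drive is above baseline; trailing cycles whose reference
drive leaves the constant-drive range are kept but flagged (no
asymptotic reference) — in the default setting exactly one such cycle
survives per ramp, i.e. the ripple outlasts the drive level at which
it started. The theoretical χ_IFA pools both chains with the falling
chain shifted by the 20 ms plateau, stamps each cycle's frequency at
its midpoint, excludes plateau cycles, and regresses by OLS. At
defaults this yields χ_IFA ≈ −2.55, −1.35 and −0.37 Hz/ms for
m = 0.4, 0.2, 0.1/ms; an independent oracle (forward-Euler DDE driven
by the actual double ramp) gives the same per-cycle frequencies and a
comparable slope at the slowest ramp, where the regression is
dominated by a handful of trailing low-drive cycles and is therefore
intrinsically fragile.

## Linear stability

The stationary state solves I_0 = I_E − K τ_m r_0 with
r_0 = f_LIF(I_0); the f-I curve is the white-noise LIF (Siegert)
integral, evaluated with the scaled complementary error function
(`erfcx`) under adaptive quadrature, returning zero when the upper
integration limit is beyond −25 (the rate underflows double
precision). The susceptibility G̃(ω) — the linear rate response to
weak periodic drive modulation — uses complex-order parabolic
cylinder functions D_ν evaluated in 30-digit arithmetic (mpmath) and
is validated by G̃(0) = df_LIF/dI, conjugate symmetry, and high-ω
decay. The Hopf point solves the pair 1 = K τ_m |G̃| (amplitude) and
0 = π + arg G̃ − ωΔ (phase): for each candidate drive the phase
condition is solved for ω by a 2 Hz scan over 100–600 Hz plus
bisection, and the drive is bisected on the amplitude condition to
1e-5. For the defaults this yields I_E^crit ≈ 1.48 (0.19 nA),
f_net ≈ 305 Hz and r_0 ≈ 15.6 Hz, with the analytic DDE onset (0.56)
well below it, consistent with the drift-based theory's stated
inapplicability near the bifurcation.

## Problem sizes and determinism

Simulation-based analyses default to N = 1000 (the constant-drive
phenomenology and the IFA slope are insensitive to N over 10²–10⁴,
which the suite checks directly); full-synchrony sweeps use six 5 s
runs and IFA experiments 50 stimulus repetitions with consecutive
seeds. Every stochastic entry point takes an explicit integer seed;
same seed, same outputs, byte-identical written files.

## Known limitations

* The Gaussian-drift theory does not describe the
  fluctuation-dominated dynamics near the Hopf bifurcation (drives
  below its applicability range); its pathological and period-2
  regimes are artifacts of the rate clipping.
* The phenomenological reset assumes the post-spike bimodality of the
  voltage distribution diffuses away within a cycle; at high noise or
  weak coupling this fails and the applicability range shrinks or
  empties (the upper constraint can switch from the single-spike to
  the subthreshold condition).
* Connectivity is all-to-all with pulse coupling and uncorrelated
  noise; sparse/random connectivity, synaptic filtering,
  conductance-based synapses, refractoriness and pyramidal-cell
  populations are out of scope.
* The anchored-chain construction for the rising ramp selects the
  longest chain; uniqueness of the anchored solution is not
  guaranteed in general, and the theoretical χ_IFA at slow ramps
  (|m| ≲ 0.1/ms) is sensitive to the inclusion of the trailing
  below-range cycle of each ramp.
* χ_IFA from simulations at small N depends on the peak-detection
  guards (analysis window, minimum separation); both are documented
  above and fixed before any comparison.
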