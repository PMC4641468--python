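# Methods

## The neuron model

The synthetic-data generator is a single-compartment conductance-based
model of a small-diameter (IB4⁺-like) DRG neuron:

    C dV/dt = −(I_Nav + I_Kdr + I_KNa + I_leak) + I_inj

with capacitance C = 16.1 pF (the measured mean for these cells) and four
currents:

* **Transient Nav** — I_Nav = g_Nav m³ h (V − E_Na), g_Nav = 600 nS,
  E_Na = +60 mV. Each activation gate is a Boltzmann with midpoint −20 mV
  and charge 3.3 e (τ_m = 0.2 ms); cubing it gives a whole-cell conductance
  activation curve with midpoint ≈ −10 mV and effective charge ≈ 4.1 e, the
  values obtained from Boltzmann fits of the peak inward current in these
  neurons. Inactivation is a single Boltzmann gate (midpoint −35 mV, charge
  3 e) with a bell-shaped time constant
  τ_h(V) = 1 + 100·exp(−((V + 35)/8)²) ms: slow in the subthreshold window,
  fast both during the spike and at recovery potentials. The slow
  subthreshold inactivation is what lets 40 ms voltage ramps and 20 ms
  current steps see high Nav availability while the resting state is
  governed by steady-state inactivation — the behavior of
  slowly-inactivating (TTX-resistant-like) sensory-neuron Na currents.
* **Delayed-rectifier K** — I_Kdr = g_K n (V − E_K), g_K = 50 nS,
  E_K = −80 mV, single Boltzmann gate (midpoint −15 mV, charge 3.5 e,
  τ_n = 4 ms). Its magnitude sets both the repolarization and the upper end
  of the repetitive-firing range (no depolarization block below 300 pA).
* **Passive leak** — 1.0 nS at −52 mV, consistent with the ~GΩ input
  resistance measured with a −60 → −70 mV step.
* **K_Na** — I_KNa = g_KNa_max p (V − E_K) with g_KNa_max = 69 nS, the
  average whole-cell K_Na conductance activated by 70 mM pipette Na⁺. The
  open probability p relaxes with τ = 4 ms toward a Hill function of the
  submembrane Na⁺ concentration (EC50 = 40 mM, Hill coefficient 3.5; these
  are configurable — the literature only brackets the activation threshold
  above ~10 mM). The channel is treated as voltage independent from −80 to
  −20 mV, matching the weak voltage dependence of the excised-patch
  activity; an optional flag adds a mild (0.1 e) voltage dependence.

**Submembrane Na⁺.** A thin shell (default 1.5 fl) integrates Nav influx
and relaxes first order (τ = 25 ms) toward the pipette-set resting
concentration. One pA·ms into 1.5 fl raises shell [Na⁺] by ~6.9 µM. This
is the coupling that makes K_Na an activity-dependent brake: Na⁺ entering
through Nav channels at the foot of the spike raises the shell
concentration and recruits K_Na before and between spikes. How native K_Na
senses Na⁺ influx is genuinely unresolved; the shell model is one
admissible reading, chosen because it produces the observed
constellation (lower rheobase, more negative threshold, steeper f–I, more
negative ramp zero crossing in K_Na-null cells) from a single mechanism.

**Why the activation lag.** With strictly instantaneous Hill coupling
(τ = 0, which remains available) the shell concentration spikes *during*
the AP upstroke, and the resulting K_Na surge depresses the peak of dV/dt.
Because the phase-plane threshold is defined relative to peak dV/dt, that
artifact inverts the WT/K_Na-null threshold ordering. A few milliseconds of
activation lag — physiologically reasonable for Slack gating — decouples
the upstroke from the foot and removes the artifact.

**Dialysis and rundown.** In voltage clamp the K_Na conductance carries the
factor D(t) = (1 − e^(−t/τ_eq)) · e^(−t/τ_run) with τ_eq = 60 s (plateau
near 3 min after break-in) and τ_run = 900 s (marked loss by 30 min). At
hyperpolarized potentials, where Nav influx is negligible, the simulated
difference current equals the closed form
g_max · Hill([Na]_pip) · D(t) · ΔV exactly; tests exploit this as an
arithmetic oracle. Current-clamp recordings (0 or 10 mM pipette Na⁺) do not
apply D(t): their K_Na is driven by the shell.

**Cs⁺ block.** 20 mM extracellular Cs⁺ multiplies both K currents by
1 − f(V), f(V) = 1 − A/(1 + exp(−zF(V − V_h)/RT)) with A = 0.39,
V_h = −82.2 mV, z = 0.68 e — the fitted voltage-dependent block of the K_Na
current, implying 61% voltage-independent inhibition at depolarized
potentials.

**Integration.** Fixed-step: forward Euler for V and shell Na⁺,
exponential Euler for the gates, dt = 0.01 ms with recordings decimated to
the protocol sample interval (default 0.05 ms, i.e. 20 kHz). Halving dt
changes AP counts by at most one for the standard protocols (tested). A
state that leaves the finite range (or |V| > 10⁶ mV) raises an integration
error naming the time point. Noise is additive Gaussian *observation*
noise on the recorded signal (0.3 mV current clamp, 5 pA voltage clamp),
not process noise — the dynamics stay deterministic, which keeps the
closed-form oracles exact.

**Single channels.** Two-state Markov gating (mean open time 4 ms, closed
time set by the Hill open probability of the bath Na⁺), unitary current
127 pS × (V − E_K) with E_K = +18.35 mV for the inside-out solution pair
(152.5 mM K⁺ out / 73.6 mM in). The state is point-sampled from the
continuous-time process, so empirical open fractions are unbiased.

**Cohorts.** Cells draw mean-preserving log-normal perturbations
(default CV 0.15) of the maximal conductances and capacitance, one seeded
substream per cell. The perturbation draws are consumed whether or not a
parameter is active, so cohorts generated from the same seed are matched
cell by cell across genotypes — WT vs K_Na-null comparisons can be run
paired. "dKO" and "Slo2.2KO" templates have g_KNa = 0; "Slo2.1KO" is
indistinguishable from WT, as observed.

## Analysis choices

* Plateau windows: last 25% of each step segment, excluding 2 ms of
  clamp settling; baselines likewise from the pre-step segment.
* Difference current is plateau mean minus pre-step baseline mean; inward
  negative.
* Fractional Cs⁺ inhibition is computed on total current by default; an
  optional 0-Na⁺ baseline record isolates the Na⁺-dependent component.
  The end-to-end block fit in the pipeline uses the baseline-subtracted
  component over −125…−55 mV, below the delayed-rectifier activation
  range; including more depolarized steps lets Kdr and the steady Nav
  window bias the fraction.
* All Boltzmann-type fits (Cs⁺ block, chord-conductance activation) share
  the RT/F slope at the configured temperature (default 19 °C,
  RT/F ≈ 25.17 mV) and multi-start over the midpoint to avoid local
  minima; degenerate data (voltage-independent block, step-like
  activation) are flagged rather than rejected.
* dV/dt is a centered difference on a 5-point moving-average-smoothed
  trace; the threshold is the last upward crossing of the stated fraction
  (default 10%) of peak dV/dt before the dV/dt peak of the first AP,
  linearly interpolated. Thresholds in the cohort pipeline are measured on
  a fixed-amplitude sweep (smallest spiking level ≥ 100 pA) so stimulus
  strength does not confound the genotype comparison.
* AP detection: local maxima above 0 mV preceded by dV/dt ≥ 10 mV/ms
  within 2 ms, with a 2 ms refractory separation.
* AHP windows: 50 ms after single APs, 1 s after trains (measured from the
  end of the last pulse, relative to the pre-train baseline).
* Rheobase: smallest amplitude of a 20 ms step family that spikes;
  the bisection variant reproduces an exhaustive scan on the same grid
  (default 2 pA).
* Ramp zero crossing: command voltage of the last outward→inward
  transition before the inward-current minimum, interpolated; for monotone
  (ohmic) currents the first zero crossing is returned. The default ramp
  runs −60 → −5 mV in 40 ms; at a −20 mV end point the Nav surge is
  marginal against the K_Na feedback in WT cells and the crossing is not
  robust.
* Statistics follow the original reporting convention: two-sample KS (exact p when
  n·m ≤ 10⁴, asymptotic otherwise), and a two-tailed unpaired
  pooled-variance t test when either group has n < 10. No
  multiple-testing correction.
* The "modified GHK conductance equation" behind the resting-potential
  calculation is implemented in its chord (conductance-weighted-reversal)
  form, which reproduces the printed −52.4 mV baseline and ~3.3 mV
  hyperpolarization exactly. For the expected K_Na current at −50 mV the
  sweep offers both the ohmic reading g·(V − E_K) (≈ 4.8 pA at 0.16 nS)
  and a GHK-rectified reading scaled to the same chord conductance
  (≈ 1.7× larger); the published ~8 pA figure sits near the latter, but
  neither is asserted as ground truth.

## What the generator does and does not emulate

It reproduces: the growth of the Na⁺-dependent background current over
~3 min of dialysis and its rundown by 30 min, with Nav transients
unaffected; the voltage dependence of Cs⁺ block; ~127 pS weakly
voltage-dependent single channels; and the excitability phenotype of K_Na
loss (lower rheobase, more negative dV/dt threshold and ramp zero
crossing, higher AP counts at matched injections, slightly depolarized
rest; no slow AHP develops over 7.1 Hz trains because the shell clears in
tens of milliseconds).

Known gaps relative to real recordings: the phase-plane threshold
difference between genotypes is small (~0.1–0.2 mV at 100 pA vs several mV
in real cells) — with a simple Nav foot the shell receives little Na⁺
before the upstroke, which is precisely the unresolved coupling question;
the model's post-spike K_Na deepens the fast AHP by several mV in WT
cells, whereas real WT/null AHPs are indistinguishable; AP half-widths are
narrower than the measured ~5 ms (a single fast Kdr stands in for the real
K-current mix); and cohort effect sizes are design choices, not fitted
quantities. Passing tests therefore demonstrate that the analysis chain
recovers what the generator puts in and reproduces the reported orderings
and closed-form anchors, not that the model is a quantitative digital twin
of a DRG neuron.

## Problem sizes

Default test and pipeline runs use cohorts of ~10–12 cells, 1 s f–I
sweeps at four amplitudes, 20 ms rheobase families on 4–10 pA grids, and
30 s single-channel records at four voltages — sizes at which every
quantity of interest is stable under reseeding while a full run stays in
the seconds-to-minutes range on one CPU.
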