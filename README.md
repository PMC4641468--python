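# kna-ephys

Quantification and simulation of the sodium-activated potassium (K_Na)
current of small-diameter dorsal root ganglion (DRG) neurons.

Slo2.2 (Slack, *Kcnt1*) channels carry a Na⁺-dependent background K⁺
current in mouse DRG neurons. With Na⁺ in the patch pipette this current
appears over the first minutes of whole-cell dialysis as a large "leak"
conductance; losing it (genetically, or by extracellular Cs⁺ block) lowers
rheobase, shifts the phase-plane spike threshold to more negative
potentials, and increases firing — K_Na acts as a brake on action-potential
initiation rather than shaping the afterhyperpolarization. This package is
for electrophysiologists who want those analyses as tested, scriptable
code, together with a conductance-based DRG neuron simulator that generates
current-clamp, voltage-clamp and excised-patch single-channel recordings
with the statistical structure the analyses assume, for wild-type-like and
K_Na-null ("dKO"-like) cells.

## What it computes

* **Leak quantification** — difference current ΔI of −80 → −120 mV steps;
  its dialysis time course ΔI(t) ∝ (1 − e^(−t/τ_eq)) e^(−t/τ_rundown);
  fractional Cs⁺ inhibition and the voltage-dependent block fit
  f(V) = 1 − A / (1 + exp(−zF(V − V_h)/RT)).
* **Excitability features** — AP detection, f–I curves, rheobase (20 ms
  steps, exhaustive or bisection), dV/dt threshold (voltage where dV/dt
  reaches 10% of its peak), AP peak/half-width/AHP, input resistance,
  ramp zero-crossing voltage, post-train AHP amplitudes.
* **Closed-form biophysics** — chord-conductance resting potential
  V_m = Σ gᵢEᵢ / Σ gᵢ and the effect of adding a small g_KNa; Nernst
  potentials; Boltzmann chord-conductance activation fits; linear resting
  conductance; single-channel slope conductance from all-points-histogram
  amplitudes.
* **Cohort statistics** — two-sample Kolmogorov–Smirnov (switching to an
  unpaired Student's t test when a group has n < 10) and a
  publication-style summary table.

## Worked example

Simulate a wild-type cell with 70 mM pipette Na⁺ and measure the leak
difference current at five times after break-in:

```python
from kna_ephys import standard_protocols, template_params
from kna_ephys.simulate import simulate_voltage_clamp, kna_dialysis_conductance
from kna_ephys.leak import leak_difference_current

params = template_params("WT")
proto = standard_protocols()["leak_step"]            # -80 -> -120 mV step
rec = simulate_voltage_clamp(params, proto, pipette_na_mm=70.0,
                             times_since_breakin_s=(30, 90, 180, 600, 1800),
                             seed=1)
for s in rec.sweeps["stim"]:
    g = kna_dialysis_conductance(params, 70.0, s.time_since_breakin_s)
    print(f"t={s.time_since_breakin_s:6.0f} s  dI={leak_difference_current(s):8.1f} pA"
          f"  g_KNa={g:6.2f} nS")
```

```
t=    30 s  dI=  -960.0 pA  g_KNa= 23.01 nS
t=    90 s  dI= -1739.5 pA  g_KNa= 42.51 nS
t=   180 s  dI= -1922.1 pA  g_KNa= 47.04 nS
t=   600 s  dI= -1281.9 pA  g_KNa= 31.05 nS
t=  1800 s  dI=  -367.4 pA  g_KNa=  8.18 nS
```

The Na⁺-dependent current grows to nanoamp scale over ~3 minutes of
dialysis and runs down by 30 minutes; dividing ΔI by the −40 mV step
recovers the closed-form K_Na conductance (plus the 1 nS passive leak).

The chord-conductance model reproduces the resting-potential arithmetic
directly:

```python
from kna_ephys import ChordModel, chord_vm
model = ChordModel()                      # g_K=0.7, g_Na=0.165, g_Cl=0.3 nS
print(chord_vm(model))                    # -52.45 mV
print(chord_vm(model.with_kna(0.16)))     # -55.77 mV, ~3.3 mV hyperpolarized
```

A full simulate → analyze → compare run (cohorts of both genotypes,
feature table, leak time course, Cs⁺ block fit, chord table, ordering
checks) is one command:

```sh
kna-ephys run --seed 1 --out report
```

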