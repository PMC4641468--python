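"""Closed-form biophysical calculations.

Chord-conductance resting-potential model (and the sweep of a hypothetical
KNa conductance added to it), Nernst potentials, Boltzmann chord-conductance
activation fits, linear resting-conductance fits, and single-channel
conductance estimation from unitary current amplitudes.

The chord model treats the resting potential as the conductance-weighted
average of the branch reversal potentials,

    V_m = sum(g_i * E_i) / sum(g_i),

equivalently the zero of the total ionic current sum(g_i * (V - E_i)).
With the default resting branches (g_K = 0.7 nS at -80 mV, g_Na = 0.165 nS
at +60 mV, g_Cl = 0.3 nS at -50 mV) this gives a basal potential of
-52.4 mV, and adding 0.16 nS of KNa conductance at E_K hyperpolarizes the
cell by ~3.3 mV — the scale of resting-potential difference seen between
WT and KNa-null neurons.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .constants import DEFAULT_TEMPERATURE_C, rt_over_f
from .datatypes import BoltzmannFit, ChordModel, SingleChannelRecord

__all__ = [
    "chord_vm",
    "gkna_sweep",
    "nernst",
    "ghk_current_scaled",
    "boltzmann",
    "boltzmann_chord_fit",
    "linear_conductance_fit",
    "single_channel_conductance",
    "unitary_amplitude",
]


def chord_vm(model: ChordModel) -> float:
    """Resting potential (mV) of a chord-conductance model."""
    branches = model.all_branches()
    g_total = sum(g for _, g, _ in branches)
    if g_total <= 0:
        raise ValueError("total conductance must be positive")
    return sum(g * e for _, g, e in branches) / g_total


def nernst(c_out_mm: float, c_in_mm: float, valence: int = 1,
           temperature_c: float = DEFAULT_TEMPERATURE_C) -> float:
    """Nernst equilibrium potential (mV), E = (RT/zF) ln(c_out/c_in)."""
    if c_out_mm <= 0 or c_in_mm <= 0:
        raise ValueError("concentrations must be positive")
    if valence == 0:
        raise ValueError("valence must be non-zero")
    return rt_over_f(temperature_c) / valence * math.log(c_out_mm / c_in_mm)


def ghk_current_scaled(v_mv, g_chord_ns: float, k_in_mm: float = 135.0,
                       k_out_mm: float = 5.6,
                       temperature_c: float = DEFAULT_TEMPERATURE_C):
    """Goldman-Hodgkin-Katz K current (pA) scaled to a chord conductance.

    The GHK flux equation rectifies outwardly for physiological K gradients;
    the permeability is chosen so the slope conductance at E_K equals
    ``g_chord_ns``. This provides the alternative reading of "expected KNa
    current" in which a given chord conductance produces a larger outward
    current at potentials positive to E_K than the ohmic g*(V - E_K).
    """
    rt_f = rt_over_f(temperature_c)

    def flux(v):
        u = np.asarray(v, dtype=float) / rt_f
        u = np.where(np.abs(u) < 1e-9, 1e-9, u)
        return u * (k_in_mm - k_out_mm * np.exp(-u)) / (1.0 - np.exp(-u))

    e_k = nernst(k_out_mm, k_in_mm, 1, temperature_c)
    dv = 1e-3
    slope = (flux(e_k + dv) - flux(e_k - dv)) / (2 * dv)  # per mV
    scale = g_chord_ns / slope
    out = scale * flux(v_mv)
    return float(out) if np.isscalar(v_mv) else out


def gkna_sweep(model: Optional[ChordModel] = None, increment_ns: float = 0.02,
               n_steps: int = 26, g_max_kna_ns: float = 69.0,
               eval_voltage_mv: float = -50.0,
               current_mode: str = "chord") -> pd.DataFrame:
    """Sweep a hypothetical KNa conductance added to the chord model.

    For each g_KNa from 0 in ``increment_ns`` steps the table reports the
    membrane potential, total conductance, effective open probability
    Po = g_KNa / g_max, and the expected KNa current at ``eval_voltage_mv``.
    ``current_mode="chord"`` uses the ohmic g*(V - E_K);
    ``current_mode="ghk"`` uses the GHK-rectified current scaled to the same
    chord conductance (roughly 1.7x larger at -50 mV) — the in-between
    values reported for this calculation are consistent with either reading,
    so both are provided.
    """
    if increment_ns <= 0:
        raise ValueError("increment must be positive")
    if current_mode not in ("chord", "ghk"):
        raise ValueError(f"unknown current mode {current_mode!r}")
    model = model or ChordModel()
    rows = []
    for k in range(n_steps):
        g = k * increment_ns
        m = model.with_kna(g)
        if current_mode == "chord":
            i_kna = g * (eval_voltage_mv - model.e_k_mv)
        else:
            i_kna = ghk_current_scaled(eval_voltage_mv, g)
        rows.append({
            "g_kna_ns": g,
            "vm_mv": chord_vm(m),
            "g_total_ns": m.total_conductance_ns(),
            "po": g / g_max_kna_ns,
            "i_kna_pa": i_kna,
        })
    return pd.DataFrame(rows)


def boltzmann(v_mv, v_half_mv: float, z: float,
              temperature_c: float = DEFAULT_TEMPERATURE_C):
    """Two-state Boltzmann activation, 1 / (1 + exp(-zF(V - V_h)/RT))."""
    slope = rt_over_f(temperature_c) / z
    v = np.asarray(v_mv, dtype=float)
    out = 1.0 / (1.0 + np.exp(-(v - v_half_mv) / slope))
    return float(out) if np.isscalar(v_mv) else out


def boltzmann_chord_fit(iv: Sequence, reversal_mv: float = 75.0,
                        temperature_c: float = DEFAULT_TEMPERATURE_C) -> BoltzmannFit:
    """Boltzmann fit of chord-conductance activation from peak currents.

    ``iv`` is a sequence of (voltage_mv, peak_current_pa); currents are
    converted to chord conductances g = I / (V - E_rev) with the assumed
    reversal, then fit with g(V) = g_max / (1 + exp(-zF(V - V_h)/RT)),
    multi-starting over V_h. Data approaching a step function are fit at the
    bound and flagged ``steep_flag``.
    """
    pts = [(float(v), float(i)) for v, i in iv]
    if len({v for v, _ in pts}) < 5:
        raise ValueError("need at least 5 distinct voltages")
    v = np.array([p[0] for p in pts])
    i = np.array([p[1] for p in pts])
    if np.any(v == reversal_mv):
        raise ValueError("voltage equals the assumed reversal; "
                         "chord conversion undefined")
    g = i / (v - reversal_mv)
    if np.allclose(g, 0.0):
        raise RuntimeError("all chord conductances are zero; nothing to fit")
    rt_f = rt_over_f(temperature_c)
    z_hi = 50.0

    def model(vv, gmax, vh, z):
        return gmax / (1.0 + np.exp(-z * (vv - vh) / rt_f))

    best = None
    for vh0 in np.arange(v.min(), v.max() + 1.0, 10.0):
        for z0 in (1.0, 4.0, 8.0):
            try:
                popt, pcov = curve_fit(
                    model, v, g, p0=(max(g.max(), 1e-6), vh0, z0),
                    bounds=([1e-9, v.min() - 100.0, 1e-3],
                            [np.inf, v.max() + 100.0, z_hi]),
                    maxfev=20000)
            except RuntimeError:
                continue
            resid = float(np.sqrt(np.sum((g - model(v, *popt)) ** 2)))
            if best is None or resid < best[1]:
                best = (popt, resid, pcov)
    if best is None:
        raise RuntimeError("Boltzmann fit did not converge from any start")
    (gmax, vh, z), resid, pcov = best
    return BoltzmannFit(g_max_ns=float(gmax), v_half_mv=float(vh), z=float(z),
                        reversal_mv=reversal_mv, temperature_c=temperature_c,
                        residual_norm=resid, covariance=pcov,
                        steep_flag=z > 0.9 * z_hi)


def linear_conductance_fit(iv: Sequence,
                           v_range: tuple = (-120.0, -60.0)):
    """Ordinary least-squares conductance over a voltage range.

    Fits I = g*V + b to the (voltage mV, steady-state current pA) points
    inside ``v_range`` and returns (g_ns, intercept_pa). Requires at least
    3 in-range points.
    """
    pts = [(float(v), float(i)) for v, i in iv
           if v_range[0] <= v <= v_range[1]]
    if len(pts) < 3:
        raise ValueError(f"need at least 3 points in {v_range}, got {len(pts)}")
    v = np.array([p[0] for p in pts])
    i = np.array([p[1] for p in pts])
    g, b = np.polyfit(v, i, 1)
    return float(g), float(b)


def unitary_amplitude(record: SingleChannelRecord, bins: int = 200) -> float:
    """Unitary current amplitude (pA) from an all-points histogram.

    The closed and open levels appear as two peaks; each is refined by a
    Gaussian fit around the local maximum and the amplitude is their
    separation, signed like the open-level current.
    """
    x = record.current_pa
    counts, edges = np.histogram(x, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    # modest smoothing so shot noise does not split peaks
    ksm = np.ones(3) / 3
    smooth = np.convolve(counts, ksm, mode="same")
    min_height = max(5.0, 0.01 * smooth.max())
    peaks, _ = find_peaks(smooth, height=min_height,
                          distance=max(3, bins // 20))
    if len(peaks) < 2:
        raise RuntimeError("histogram does not show two separated levels")
    # the two most populated peaks are the closed and open levels
    top2 = sorted(sorted(peaks, key=lambda k: smooth[k])[-2:])

    def refine(k):
        lo, hi = max(0, k - bins // 20), min(len(centers), k + bins // 20 + 1)
        c, mu, sd = counts[k], centers[k], 2 * (centers[1] - centers[0])
        try:
            popt, _ = curve_fit(
                lambda xx, a, m, s: a * np.exp(-0.5 * ((xx - m) / s) ** 2),
                centers[lo:hi], counts[lo:hi], p0=(c, mu, sd), maxfev=5000)
            return popt[1]
        except RuntimeError:
            return mu

    mus = sorted(refine(k) for k in top2)
    # closed level is the one nearer zero current
    closed, open_ = (mus[1], mus[0]) if abs(mus[1]) < abs(mus[0]) else (mus[0], mus[1])
    return float(open_ - closed)


def single_channel_conductance(amplitudes: Sequence):
    """Slope conductance and reversal from unitary amplitudes.

    ``amplitudes`` is a sequence of (voltage_mv, unitary_current_pa); a
    linear regression i = gamma*(V - E) yields the unitary conductance
    gamma (pS) and the reversal E (mV).
    """
    pts = [(float(v), float(i)) for v, i in amplitudes]
    if len({v for v, _ in pts}) < 2:
        raise ValueError("need at least two distinct voltages")
    v = np.array([p[0] for p in pts])
    i = np.array([p[1] for p in pts])
    slope, intercept = np.polyfit(v, i, 1)
    if slope == 0:
        raise ValueError("zero slope; reversal undefined")
    return float(slope * 1e3), float(-intercept / slope)  # nS/mV -> pS
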