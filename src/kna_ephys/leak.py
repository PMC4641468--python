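"""Quantification of the Na-dependent background (KNa) current.

The KNa current of small-diameter DRG neurons appears as a background "leak"
conductance: with Na in the pipette, hyperpolarizing steps from -80 to
-120 mV evoke a difference current that grows over the first minutes of
whole-cell dialysis and slowly runs down. Extracellular Cs blocks the
current with a voltage-dependent fraction described by

    f(V) = 1 - A / (1 + exp(-zF(V - V_h)/RT))

so that block is complete at very negative potentials and relaxes to the
voltage-independent floor 1 - A at depolarized potentials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .constants import DEFAULT_TEMPERATURE_C, rt_over_f
from .datatypes import BlockFit, CellRecord, Sweep

__all__ = [
    "LeakMeasurement",
    "InsufficientDataError",
    "leak_difference_current",
    "leak_time_course",
    "fit_dialysis_time_course",
    "fractional_inhibition",
    "fit_cs_block",
    "eval_cs_block",
]


class InsufficientDataError(ValueError):
    """Too few data points for the requested fit or summary."""


@dataclass
class LeakMeasurement:
    """Difference current for one -80 -> -120 mV step sweep."""

    delta_i_pa: float
    time_since_breakin_s: float
    bath: str = "control"


def _step_bounds(sweep: Sweep):
    """Indices of the command step (first departure from holding and back)."""
    cmd = sweep.command
    changed = np.where(cmd != cmd[0])[0]
    if len(changed) == 0:
        raise ValueError("command waveform contains no step")
    return int(changed[0]), int(changed[-1]) + 1


def _plateau_window(i0: int, i1: int, dt_ms: float, settle_ms: float = 2.0,
                    fraction: float = 0.25):
    """Last ``fraction`` of a segment, excluding capacitive settling."""
    n = i1 - i0
    start = i1 - max(1, int(round(n * fraction)))
    start = max(start, i0 + int(round(settle_ms / dt_ms)))
    return start, i1


def leak_difference_current(sweep: Sweep,
                            step_window: Optional[tuple] = None) -> float:
    """Difference current (pA) of a hyperpolarizing-step sweep.

    Mean current during the step plateau minus mean current during the
    pre-step baseline; inward current is negative. By default the plateau
    window is the last 25% of the step and the baseline the last 25% of the
    pre-step segment, both excluding 2 ms of capacitive settling; an explicit
    ``step_window`` (t0_ms, t1_ms) overrides the plateau window.
    """
    dt = sweep.dt_ms
    i0, i1 = _step_bounds(sweep)
    if step_window is not None:
        j0 = int(round(step_window[0] / dt))
        j1 = int(round(step_window[1] / dt))
        if j0 < 0 or j1 > len(sweep.recorded) or j0 >= j1:
            raise IndexError("step window lies outside the sweep")
    else:
        j0, j1 = _plateau_window(i0, i1, dt)
    b0, b1 = _plateau_window(0, i0, dt)
    return float(sweep.recorded[j0:j1].mean() - sweep.recorded[b0:b1].mean())


def _rise_decay(t_s, amp, tau_eq, tau_run):
    return amp * (1.0 - np.exp(-t_s / tau_eq)) * np.exp(-t_s / tau_run)


def fit_dialysis_time_course(times_s: np.ndarray, delta_i_pa: np.ndarray):
    """Fit |dI|(t) = amp * (1 - exp(-t/tau_eq)) * exp(-t/tau_run).

    Returns (amp_pa, tau_eq_s, tau_run_s). Requires at least 3 points.
    """
    t = np.asarray(times_s, dtype=float)
    y = np.abs(np.asarray(delta_i_pa, dtype=float))
    if len(t) < 3:
        raise InsufficientDataError("need at least 3 time points")
    amp0 = max(y.max(), 1.0)
    span = max(t.max(), 1.0)
    best = None
    for tau0 in (span / 20, span / 5, span):
        try:
            popt, _ = curve_fit(
                _rise_decay, t, y, p0=(amp0, tau0, 10 * span),
                bounds=([0.0, 1e-3, 1e-2], [np.inf, np.inf, np.inf]),
                maxfev=20000)
        except RuntimeError:
            continue
        resid = float(np.sum((y - _rise_decay(t, *popt)) ** 2))
        if best is None or resid < best[1]:
            best = (popt, resid)
    if best is None:
        raise RuntimeError("dialysis time-course fit failed to converge")
    amp, tau_eq, tau_run = best[0]
    return float(amp), float(tau_eq), float(tau_run)


def leak_time_course(cell: CellRecord, protocol_name: str = "stim",
                     step_window: Optional[tuple] = None):
    """Difference-current time course of one cell's repeated leak steps.

    Returns ``(measurements, fit)`` where measurements is the time-ordered
    list of :class:`LeakMeasurement` and fit the ``(amp, tau_eq, tau_run)``
    triple of the dialysis model fitted to their magnitudes.
    """
    sweeps = cell.sweeps.get(protocol_name, [])
    if len(sweeps) < 3:
        raise InsufficientDataError(
            f"need at least 3 leak sweeps, got {len(sweeps)}")
    meas = sorted(
        (LeakMeasurement(leak_difference_current(s, step_window),
                         s.time_since_breakin_s, s.bath) for s in sweeps),
        key=lambda m: m.time_since_breakin_s)
    t = np.array([m.time_since_breakin_s for m in meas])
    y = np.array([m.delta_i_pa for m in meas])
    fit = fit_dialysis_time_course(t, y)
    return meas, fit


def _steady_state_iv(cell: CellRecord, protocol_name: str):
    """(voltages, plateau currents) from a step-family record, averaged over
    sweeps sharing a level."""
    sweeps = cell.sweeps[protocol_name]
    by_level: dict = {}
    for s in sweeps:
        i0, i1 = _step_bounds(s)
        j0, j1 = _plateau_window(i0, i1, s.dt_ms)
        level = float(s.command[i0:i1].mean()) if s.level is None else float(s.level)
        by_level.setdefault(level, []).append(float(s.recorded[j0:j1].mean()))
    vs = sorted(by_level)
    return (np.array(vs),
            np.array([np.mean(by_level[v]) for v in vs]))


def fractional_inhibition(control: CellRecord, blocked: CellRecord,
                          voltages: Optional[Sequence[float]] = None,
                          protocol_name: str = "stim",
                          baseline: Optional[CellRecord] = None,
                          noise_floor_pa: float = 5.0):
    """Fractional block f(V) = 1 - I_blocked / I_control at each step voltage.

    If a 0-Na ``baseline`` record is supplied its plateau currents are
    subtracted from both conditions first, so the fraction refers to the
    Na-dependent component only. Voltages where the control current falls
    below ``noise_floor_pa`` are excluded; fractions outside [0, 1] are
    clipped and flagged.

    Returns a list of ``(voltage_mv, fraction, clipped_flag)`` tuples.
    """
    v_c, i_c = _steady_state_iv(control, protocol_name)
    v_b, i_b = _steady_state_iv(blocked, protocol_name)
    common = np.intersect1d(v_c, v_b)
    if baseline is not None:
        v_0, i_0 = _steady_state_iv(baseline, protocol_name)
        common = np.intersect1d(common, v_0)
    if voltages is not None:
        common = np.intersect1d(common, np.asarray(voltages, dtype=float))
    out = []
    for v in common:
        ic = i_c[np.searchsorted(v_c, v)]
        ib = i_b[np.searchsorted(v_b, v)]
        if baseline is not None:
            i0 = i_0[np.searchsorted(v_0, v)]
            ic, ib = ic - i0, ib - i0
        if abs(ic) < noise_floor_pa:
            continue
        f = 1.0 - ib / ic
        clipped = not (0.0 <= f <= 1.0)
        out.append((float(v), float(min(max(f, 0.0), 1.0)), clipped))
    return out


def eval_cs_block(fit: BlockFit, v_mv):
    """Evaluate the fractional-inhibition curve f(V) of a block fit.

    Limits: f -> 1 as V -> -inf, f -> 1 - A as V -> +inf, and
    f(V_h) = 1 - A/2.
    """
    slope = rt_over_f(fit.temperature_c) / fit.z if fit.z > 0 else np.inf
    v = np.asarray(v_mv, dtype=float)
    with np.errstate(over="ignore"):
        f = 1.0 - fit.a / (1.0 + np.exp(-(v - fit.v_half_mv) / slope))
    return float(f) if np.isscalar(v_mv) else f


def fit_cs_block(points, temperature_c: float = DEFAULT_TEMPERATURE_C) -> BlockFit:
    """Least-squares fit of the voltage-dependent block curve.

    ``points`` is a sequence of (voltage_mv, fraction) pairs (a third,
    ignored element per point is tolerated so the output of
    :func:`fractional_inhibition` can be passed directly). A multi-start
    search over the V_h grid avoids local minima. A fit whose voltage-
    dependent amplitude collapses (A -> 0) is flagged ``degenerate``: V_h
    and z are then unidentifiable.
    """
    pts = [(float(p[0]), float(p[1])) for p in points]
    if len({v for v, _ in pts}) < 4:
        raise InsufficientDataError("need at least 4 distinct voltages")
    v = np.array([p[0] for p in pts])
    f = np.array([p[1] for p in pts])
    rt_f = rt_over_f(temperature_c)

    def model(vv, a, vh, z):
        return 1.0 - a / (1.0 + np.exp(-z * (vv - vh) / rt_f))

    best = None
    for vh0 in np.arange(v.min() - 40.0, v.max() + 41.0, 20.0):
        for z0 in (0.3, 0.7, 1.5):
            try:
                popt, pcov = curve_fit(
                    model, v, f, p0=(min(max(1.0 - f.min(), 0.05), 1.0), vh0, z0),
                    bounds=([0.0, -300.0, 1e-3], [1.0, 150.0, 20.0]),
                    maxfev=20000)
            except RuntimeError:
                continue
            resid = float(np.sqrt(np.sum((f - model(v, *popt)) ** 2)))
            if best is None or resid < best[1]:
                best = (popt, resid, pcov)
    if best is None:
        raise RuntimeError(
            "block fit did not converge from any start "
            f"(n={len(pts)}, f range {f.min():.3g}..{f.max():.3g})")
    (a, vh, z), resid, pcov = best
    degenerate = a < 1e-3 or float(np.ptp(model(v, a, vh, z))) < 1e-6
    return BlockFit(a=float(a), v_half_mv=float(vh), z=float(z),
                    temperature_c=temperature_c, residual_norm=resid,
                    covariance=pcov, degenerate=degenerate)
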