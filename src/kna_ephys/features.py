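"""Excitability measures from current-clamp and ramp recordings.

Implements the feature set used to compare WT and KNa-null DRG neurons:
action-potential detection and counts (f-I curves), rheobase from 20 ms
step families, phase-plane (dV/dt) spike threshold, single-AP shape
(peak, half-width, afterhyperpolarization), input resistance, the command
voltage at which ramp-evoked current turns net inward, and post-train AHP
amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .datatypes import CellRecord, Sweep

__all__ = [
    "APEvent",
    "NoAPError",
    "NoCrossingError",
    "UnboundedRheobaseError",
    "detect_aps",
    "ap_threshold",
    "ap_shape_features",
    "rheobase",
    "rheobase_bisect",
    "fi_curve",
    "ramp_zero_crossing",
    "input_resistance",
    "train_ahp",
]


class NoAPError(ValueError):
    """The trace contains no action potential."""


class NoCrossingError(ValueError):
    """The ramp current never becomes net inward."""


class UnboundedRheobaseError(ValueError):
    """No sweep of the family elicited an action potential."""


@dataclass
class APEvent:
    """One detected action potential and its shape measures."""

    peak_time_ms: float
    peak_v_mv: float
    threshold_v_mv: Optional[float] = None
    half_width_ms: Optional[float] = None
    ahp_min_mv: Optional[float] = None
    max_dvdt_mv_per_ms: Optional[float] = None
    clipped: bool = False


def _smoothed_dvdt(sweep: Sweep, smooth_points: int = 5):
    """Centered-difference dV/dt (mV/ms) on a moving-average-smoothed trace."""
    v = sweep.recorded
    if smooth_points > 1:
        kernel = np.ones(smooth_points) / smooth_points
        pad = smooth_points // 2
        vp = np.pad(v, pad, mode="edge")
        v = np.convolve(vp, kernel, mode="valid")[: len(sweep.recorded)]
    return v, np.gradient(v, sweep.dt_ms)


def detect_aps(sweep: Sweep, peak_threshold_mv: float = 0.0,
               dvdt_threshold: float = 10.0,
               refractory_ms: float = 2.0) -> list:
    """Detect action potentials in a voltage trace.

    An AP is a local maximum exceeding ``peak_threshold_mv`` whose upstroke
    reaches at least ``dvdt_threshold`` mV/ms, with successive events
    separated by at least ``refractory_ms``.
    """
    if sweep.mode != "current_clamp":
        raise ValueError("AP detection requires a current-clamp sweep")
    v = sweep.recorded
    dt = sweep.dt_ms
    _, dvdt = _smoothed_dvdt(sweep)
    above = v > peak_threshold_mv
    # contiguous supra-threshold segments -> candidate peaks
    starts = np.where(above[1:] & ~above[:-1])[0] + 1
    ends = np.where(~above[1:] & above[:-1])[0] + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [len(v)]])
    events = []
    last_peak_t = -np.inf
    lookback = int(round(refractory_ms / dt))
    for s0, s1 in zip(starts, ends):
        ipk = s0 + int(np.argmax(v[s0:s1]))
        t_pk = sweep.time_ms[ipk]
        if t_pk - last_peak_t < refractory_ms:
            continue
        if dvdt[max(0, s0 - lookback):ipk + 1].max() < dvdt_threshold:
            continue
        events.append(APEvent(peak_time_ms=float(t_pk), peak_v_mv=float(v[ipk])))
        last_peak_t = t_pk
    return events


def ap_threshold(sweep: Sweep, fraction: float = 0.10,
                 smooth_points: int = 5) -> float:
    """Phase-plane spike threshold of the first AP (mV).

    The threshold is the membrane potential at which dV/dt last rises
    through ``fraction`` of its peak value before the dV/dt maximum of the
    first AP upstroke, linearly interpolated between samples. With
    ``fraction = 1`` this degenerates to the potential at peak dV/dt.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    events = detect_aps(sweep)
    if not events:
        raise NoAPError("trace contains no action potential")
    vsm, dvdt = _smoothed_dvdt(sweep, smooth_points)
    ipk = int(round((events[0].peak_time_ms - sweep.time_ms[0]) / sweep.dt_ms))
    idvmax = int(np.argmax(dvdt[: ipk + 1]))
    target = fraction * dvdt[idvmax]
    below = np.where(dvdt[:idvmax] < target)[0]
    if len(below) == 0:
        return float(vsm[idvmax]) if fraction >= 1.0 else float(vsm[0])
    k = int(below[-1])
    if dvdt[k + 1] == dvdt[k]:
        return float(vsm[k + 1])
    w = (target - dvdt[k]) / (dvdt[k + 1] - dvdt[k])
    return float(vsm[k] + w * (vsm[k + 1] - vsm[k]))


def ap_shape_features(sweep: Sweep, fraction: float = 0.10,
                      ahp_window_ms: float = 50.0,
                      ceiling_mv: Optional[float] = None) -> APEvent:
    """Shape measures of the first AP of a sweep.

    Half-width is the duration between the half-amplitude crossings, where
    amplitude is peak minus threshold; the AHP is the voltage minimum within
    ``ahp_window_ms`` after the peak. A peak at the recording ceiling is
    flagged ``clipped``.
    """
    events = detect_aps(sweep)
    if not events:
        raise NoAPError("trace contains no action potential")
    ev = events[0]
    v = sweep.recorded
    dt = sweep.dt_ms
    ipk = int(round((ev.peak_time_ms - sweep.time_ms[0]) / dt))
    ev.threshold_v_mv = ap_threshold(sweep, fraction=fraction)
    _, dvdt = _smoothed_dvdt(sweep)
    ev.max_dvdt_mv_per_ms = float(dvdt[: ipk + 1].max())

    half = ev.threshold_v_mv + 0.5 * (ev.peak_v_mv - ev.threshold_v_mv)
    up = ipk
    while up > 0 and v[up - 1] > half:
        up -= 1
    down = ipk
    while down < len(v) - 1 and v[down + 1] > half:
        down += 1
    # linear interpolation at both crossings
    t_up = sweep.time_ms[up]
    if up > 0 and v[up] != v[up - 1]:
        t_up -= dt * (v[up] - half) / (v[up] - v[up - 1])
    t_down = sweep.time_ms[down]
    if down < len(v) - 1 and v[down] != v[down + 1]:
        t_down += dt * (v[down] - half) / (v[down] - v[down + 1])
    ev.half_width_ms = float(t_down - t_up)

    j1 = min(len(v), ipk + int(round(ahp_window_ms / dt)))
    ev.ahp_min_mv = float(v[ipk:j1].min())
    if ceiling_mv is not None and ev.peak_v_mv >= ceiling_mv:
        ev.clipped = True
    return ev


def _sweep_level(sweep: Sweep) -> float:
    if sweep.level is not None:
        return float(sweep.level)
    base = sweep.command[0]
    dev = sweep.command - base
    return float(dev[np.argmax(np.abs(dev))])


def rheobase(cell: CellRecord, protocol_name: str = "stim") -> float:
    """Smallest injected current (pA) of a step family that elicits an AP."""
    sweeps = sorted(cell.sweeps[protocol_name], key=_sweep_level)
    for s in sweeps:
        if detect_aps(s):
            return _sweep_level(s)
    raise UnboundedRheobaseError(
        "no sweep of the family elicited an action potential")


def rheobase_bisect(spikes_at: Callable[[float], bool],
                    lo_pa: float = 20.0, hi_pa: float = 300.0,
                    increment_pa: float = 2.0) -> float:
    """Rheobase by bisection against a simulator handle.

    ``spikes_at(amplitude)`` must report whether a step of that amplitude
    elicits an AP. Returns the smallest multiple of ``increment_pa`` that
    spikes, equivalent to an exhaustive scan on the same grid.
    """
    n_lo = 0  # grid index of lo_pa, assumed silent
    n_hi = int(np.ceil((hi_pa - lo_pa) / increment_pa))
    if spikes_at(lo_pa):
        return lo_pa
    if not spikes_at(lo_pa + n_hi * increment_pa):
        raise UnboundedRheobaseError(
            f"no AP up to {lo_pa + n_hi * increment_pa:g} pA")
    while n_hi - n_lo > 1:
        mid = (n_lo + n_hi) // 2
        if spikes_at(lo_pa + mid * increment_pa):
            n_hi = mid
        else:
            n_lo = mid
    return lo_pa + n_hi * increment_pa


def fi_curve(cell: CellRecord, protocol_name: str = "stim") -> list:
    """(injected current pA, AP count) per sweep of a 1 s step family."""
    sweeps = sorted(cell.sweeps[protocol_name], key=_sweep_level)
    return [(_sweep_level(s), len(detect_aps(s))) for s in sweeps]


def ramp_zero_crossing(sweep: Sweep, smooth_ms: float = 0.25) -> float:
    """Command voltage (mV) at which ramp-evoked current turns net inward.

    The current minimum inside the ramp locates the inward surge; the
    crossing is the last transition from outward to inward current before
    that minimum, linearly interpolated on the command-voltage axis. Light
    smoothing suppresses sample noise around the zero level.
    """
    if sweep.mode != "voltage_clamp":
        raise ValueError("ramp analysis requires a voltage-clamp sweep")
    cmd = sweep.command
    dcmd = np.diff(cmd)
    ramp_idx = np.where(dcmd != 0)[0]
    if len(ramp_idx) == 0:
        raise ValueError("command contains no ramp")
    r0, r1 = int(ramp_idx[0]) + 1, int(ramp_idx[-1]) + 1
    i = sweep.recorded
    nsm = max(1, int(round(smooth_ms / sweep.dt_ms)))
    if nsm > 1:
        i = np.convolve(np.pad(i, nsm // 2, mode="edge"),
                        np.ones(nsm) / nsm, mode="valid")[: len(i)]
    seg = i[r0:r1]
    vseg = cmd[r0:r1]
    imin = int(np.argmin(seg))
    if seg.min() >= 0:
        raise NoCrossingError("current never becomes net inward on the ramp")
    pos = np.where(seg[:imin] > 0)[0]
    if len(pos):
        # experimental case: outward current early in the ramp turning inward
        # at the Nav surge; take the last outward->inward transition
        k = int(pos[-1])
    else:
        # degenerate (e.g. ohmic) case: current monotone through zero; take
        # the first sign change inside the ramp
        sign_change = np.where(np.diff(np.sign(seg)) != 0)[0]
        if len(sign_change) == 0:
            raise NoCrossingError("current does not cross zero on the ramp")
        k = int(sign_change[0])
    w = seg[k] / (seg[k] - seg[k + 1])
    return float(vseg[k] + w * (vseg[k + 1] - vseg[k]))


def input_resistance(cell: CellRecord, protocol_name: str = "stim",
                     noise_floor_pa: float = 1.0) -> float:
    """Input resistance (MOhm) from a small hyperpolarizing voltage step.

    R = dV / dI between the pre-step baseline and the step plateau of a
    voltage-clamp step (the standard -60 to -70 mV protocol).
    """
    from .leak import _plateau_window, _step_bounds  # shared window logic

    sweep = cell.sweeps[protocol_name][0]
    i0, i1 = _step_bounds(sweep)
    j0, j1 = _plateau_window(i0, i1, sweep.dt_ms)
    b0, b1 = _plateau_window(0, i0, sweep.dt_ms)
    delta_v = float(sweep.command[i0:i1].mean() - sweep.command[0])
    delta_i = float(sweep.recorded[j0:j1].mean() - sweep.recorded[b0:b1].mean())
    if abs(delta_i) < noise_floor_pa:
        raise ValueError("current deflection below the noise floor; "
                         "input resistance unreliable")
    return float(delta_v / delta_i * 1e3)  # mV/pA = GOhm -> MOhm


def train_ahp(sweep: Sweep, n_pulses: int,
              window_ms: float = 1000.0) -> float:
    """Post-train AHP amplitude (mV, negative = hyperpolarized).

    Minimum voltage within ``window_ms`` after the last stimulus pulse,
    relative to the pre-train baseline. With ``n_pulses = 0`` (no stimulus)
    the AHP is zero by definition.
    """
    if n_pulses == 0:
        return 0.0
    cmd = sweep.command
    stim = np.where(cmd != cmd[0])[0]
    if len(stim) == 0:
        raise ValueError("protocol mismatch: no stimulus pulses in command")
    n_seen = 1 + int(np.sum((np.diff(stim) > 1)))
    if n_seen != n_pulses:
        raise ValueError(f"protocol mismatch: expected {n_pulses} pulses, "
                         f"command contains {n_seen}")
    dt = sweep.dt_ms
    i_end = int(stim[-1]) + 1
    baseline = float(sweep.recorded[: max(1, int(stim[0]))].mean())
    j0 = i_end
    j1 = min(len(sweep.recorded), i_end + int(round(window_ms / dt)))
    if j0 >= j1:
        raise ValueError("sweep ends before the post-train window")
    return float(sweep.recorded[j0:j1].min() - baseline)
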