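"""Compiled inner loops of the conductance-based neuron model.

Fixed-step integration (exponential Euler for the gating variables, forward
Euler for voltage and submembrane Na) with several substeps per recorded
sample. All kernels are deterministic; noise is added by the callers.
"""

import math

import numpy as np
from numba import njit


@njit(cache=True)
def hill(na, ec50, h):
    if na <= 0.0:
        return 0.0
    r = (na / ec50) ** h
    return r / (1.0 + r)


@njit(cache=True)
def _boltz(v, v_half, slope):
    # slope = RT/(zF) in mV
    return 1.0 / (1.0 + math.exp(-(v - v_half) / slope))


@njit(cache=True)
def _ipow(x, p):
    out = x
    for _ in range(p - 1):
        out *= x
    return out


@njit(cache=True)
def _ah(v, dt, h_tau_min, h_tau_amp, h_tau_vh, h_tau_k):
    # bell-shaped inactivation time constant: slow in the subthreshold window,
    # fast both during the spike and at recovery potentials
    x = (v - h_tau_vh) / h_tau_k
    tau = h_tau_min + h_tau_amp * math.exp(-x * x)
    return 1.0 - math.exp(-dt / tau)


@njit(cache=True)
def integrate_cc(i_inj, n_sub, dt,
                 c, gna, ena, m_vh, m_slope, m_pow, am, h_vh, h_slope,
                 h_tau_min, h_tau_amp, h_tau_vh, h_tau_k,
                 gk, ek, n_vh, n_slope, n_pow, an,
                 gl, el,
                 gkna, ekna, ec50, hillc, akna,
                 na_coef, ext_tau, rest_na,
                 v0, m0, h0, n0, na0, p0):
    """Current clamp: returns (v, na, fail_index).

    ``i_inj`` is the total injected current (bias + stimulus, pA) at the
    recorded sample rate, held constant across the ``n_sub`` substeps of each
    sample interval. ``fail_index`` is -1 on success, else the sample index
    at which the state became non-finite.
    """
    nsamp = i_inj.shape[0]
    v_out = np.empty(nsamp)
    na_out = np.empty(nsamp)
    v, m, h, n, na, pk = v0, m0, h0, n0, na0, p0
    for i in range(nsamp):
        v_out[i] = v
        na_out[i] = na
        if i == nsamp - 1:
            break
        inj = i_inj[i]
        for _ in range(n_sub):
            ina = gna * _ipow(m, m_pow) * h * (v - ena)
            ikdr = gk * _ipow(n, n_pow) * (v - ek)
            ikna = gkna * pk * (v - ekna)
            il = gl * (v - el)
            v += dt * (inj - (ina + ikdr + ikna + il)) / c
            influx = -ina if ina < 0.0 else 0.0
            na += dt * (influx * na_coef - (na - rest_na) / ext_tau)
            pk += (hill(na, ec50, hillc) - pk) * akna
            m += (_boltz(v, m_vh, m_slope) - m) * am
            h += (1.0 - _boltz(v, h_vh, h_slope) - h) * \
                _ah(v, dt, h_tau_min, h_tau_amp, h_tau_vh, h_tau_k)
            n += (_boltz(v, n_vh, n_slope) - n) * an
        if not (math.isfinite(v) and math.isfinite(na)) or abs(v) > 1e6:
            return v_out, na_out, i + 1
    return v_out, na_out, -1


@njit(cache=True)
def integrate_vc(v_cmd, n_sub, dt, tau_clamp,
                 c, gna, ena, m_vh, m_slope, m_pow, am, h_vh, h_slope,
                 h_tau_min, h_tau_amp, h_tau_vh, h_tau_k,
                 gk, ek, n_vh, n_slope, n_pow, an,
                 gl, el,
                 gkna_eff, ekna, ec50, hillc, akna,
                 na_coef, ext_tau, na_eq,
                 cs_on, cs_a, cs_vh, cs_slope,
                 v0, m0, h0, n0, na0, p0):
    """Voltage clamp: returns (i_recorded, na, fail_index).

    The membrane potential relaxes toward the command with time constant
    ``tau_clamp`` (imperfect clamp/settling); the recorded current is the
    ionic current plus the capacitive transient. ``gkna_eff`` already carries
    the dialysis/rundown scaling; extracellular Cs block (when ``cs_on``)
    scales the K currents by 1 - f(V).
    """
    nsamp = v_cmd.shape[0]
    i_out = np.empty(nsamp)
    na_out = np.empty(nsamp)
    v, m, h, n, na, pk = v0, m0, h0, n0, na0, p0
    aclamp = 1.0 - math.exp(-dt / tau_clamp)
    i_rec = 0.0
    for i in range(nsamp):
        cmd = v_cmd[i]
        for _ in range(n_sub):
            dv = (cmd - v) * aclamp
            icap = c * dv / dt
            v += dv
            ina = gna * _ipow(m, m_pow) * h * (v - ena)
            ikdr = gk * _ipow(n, n_pow) * (v - ek)
            ikna = gkna_eff * pk * (v - ekna)
            il = gl * (v - el)
            if cs_on:
                f = 1.0 - cs_a * _boltz(v, cs_vh, cs_slope)
                ikdr *= 1.0 - f
                ikna *= 1.0 - f
            influx = -ina if ina < 0.0 else 0.0
            na += dt * (influx * na_coef - (na - na_eq) / ext_tau)
            pk += (hill(na, ec50, hillc) - pk) * akna
            m += (_boltz(v, m_vh, m_slope) - m) * am
            h += (1.0 - _boltz(v, h_vh, h_slope) - h) * \
                _ah(v, dt, h_tau_min, h_tau_amp, h_tau_vh, h_tau_k)
            n += (_boltz(v, n_vh, n_slope) - n) * an
            i_rec = ina + ikdr + ikna + il + icap
        i_out[i] = i_rec
        na_out[i] = na
        if not (math.isfinite(v) and math.isfinite(na)) or abs(v) > 1e6:
            return i_out, na_out, i + 1
    return i_out, na_out, -1
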