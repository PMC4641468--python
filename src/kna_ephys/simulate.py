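"""Synthetic recordings from a conductance-based small-diameter DRG neuron.

The model is a single compartment with a transient Nav conductance, a
delayed-rectifier K conductance, an ohmic leak, and a Na-activated K (KNa)
conductance whose open probability is an instantaneous Hill function of the
Na concentration in a thin submembrane shell. The shell is filled by Na
influx through the Nav conductance and cleared first order toward the
pipette-set resting level, so KNa activation tracks Nav activity on a
~10 ms timescale — the coupling that lets KNa brake action-potential
initiation.

In voltage clamp the KNa conductance additionally carries the whole-cell
dialysis factor D(t) = (1 - exp(-t/tau_eq)) * exp(-t/tau_rundown): pipette Na
reaches the cell over minutes and the current slowly runs down over tens of
minutes.
"""

from __future__ import annotations

import math

import numpy as np

from . import _kernels
from .constants import FARADAY, rt_over_f
from .datatypes import (
    BlockFit,
    CellRecord,
    NeuronModelParams,
    ProtocolSpec,
    SingleChannelRecord,
    Sweep,
    template_params,
    KNA_NULL_GENOTYPES,
)

__all__ = [
    "IntegrationError",
    "CS_BLOCK_REFERENCE",
    "INSIDE_OUT_EK_MV",
    "hill_open_probability",
    "dialysis_factor",
    "kna_dialysis_conductance",
    "holding_state",
    "resting_potential",
    "simulate_current_clamp",
    "simulate_voltage_clamp",
    "simulate_single_channel",
    "make_cohort",
]

#: E_K of the inside-out patch solutions (152.5 mM K out / 73.6 mM in).
INSIDE_OUT_EK_MV = 18.35

#: Voltage dependence of 20 mM extracellular Cs block of KNa current.
CS_BLOCK_REFERENCE = BlockFit(a=0.39, v_half_mv=-82.2, z=0.68)


class IntegrationError(RuntimeError):
    """Raised when the membrane state becomes non-finite during integration."""


def hill_open_probability(na_mm, ec50_mm: float, hill: float):
    """Instantaneous KNa open probability as a Hill function of [Na+]."""
    na = np.asarray(na_mm, dtype=float)
    r = np.where(na > 0, (np.maximum(na, 0.0) / ec50_mm) ** hill, 0.0)
    out = r / (1.0 + r)
    return float(out) if np.isscalar(na_mm) else out


def dialysis_factor(t_s: float, params: NeuronModelParams) -> float:
    """Whole-cell dialysis scaling of the KNa conductance at time ``t_s``
    (seconds) after break-in: rise with the equilibration tau, decay with the
    rundown tau. Zero at break-in."""
    d = params.dialysis
    if t_s <= 0:
        return 0.0
    return (1.0 - math.exp(-t_s / d.equilibration_tau_s)) * \
        math.exp(-t_s / d.rundown_tau_s)


def kna_dialysis_conductance(params: NeuronModelParams, pipette_na_mm: float,
                             t_s: float) -> float:
    """Closed-form KNa conductance (nS) seen at hyperpolarized potentials in
    voltage clamp: gmax * Hill(pipette Na) * D(t). This is what a
    -80 -> -120 mV difference current divided by the step size estimates."""
    k = params.kna
    return k.gmax_wholecell_ns * \
        hill_open_probability(pipette_na_mm, k.na_ec50_mm, k.na_hill) * \
        dialysis_factor(t_s, params)


# ---------------------------------------------------------------------------
# kernel plumbing
# ---------------------------------------------------------------------------

def _gate_args(params: NeuronModelParams, dt: float):
    """Pack the conductance/gating arguments shared by both kernels."""
    rt_f = rt_over_f(params.temperature_c)
    nav, kdr = params.fast_nav, params.delayed_rectifier_k
    return dict(
        c=params.membrane_capacitance_pf,
        gna=nav.gmax_ns, ena=nav.e_rev_mv,
        m_vh=nav.v_half_mv, m_slope=rt_f / nav.z, m_pow=nav.act_power,
        am=1.0 - math.exp(-dt / nav.tau_act_ms),
        h_vh=nav.inact_v_half_mv, h_slope=rt_f / nav.inact_z,
        h_tau_min=nav.tau_inact_min_ms, h_tau_amp=nav.tau_inact_amp_ms,
        h_tau_vh=nav.tau_inact_v_half_mv, h_tau_k=nav.tau_inact_k_mv,
        gk=kdr.gmax_ns, ek=kdr.e_rev_mv,
        n_vh=kdr.v_half_mv, n_slope=rt_f / kdr.z, n_pow=kdr.act_power,
        an=1.0 - math.exp(-dt / kdr.tau_act_ms),
        gl=params.passive_leak.g_ns, el=params.passive_leak.e_rev_mv,
    )


def _kna_alpha(params: NeuronModelParams, dt: float) -> float:
    tau = params.kna.activation_tau_ms
    return 1.0 if tau <= 0 else 1.0 - math.exp(-dt / tau)


def _na_coef(params: NeuronModelParams) -> float:
    # mM per (pA * ms) into the submembrane shell:
    # 1 pA * 1 ms = 1e-15 C -> 1e-15/F mol, divided by the shell volume
    vol_litre = params.na_handling.shell_volume_pl * 1e-12
    return 1e-12 / (FARADAY * vol_litre)


def _steady_gates(params: NeuronModelParams, v: float):
    rt_f = rt_over_f(params.temperature_c)
    nav, kdr = params.fast_nav, params.delayed_rectifier_k
    m = 1.0 / (1.0 + math.exp(-(v - nav.v_half_mv) * nav.z / rt_f))
    h = 1.0 - 1.0 / (1.0 + math.exp(-(v - nav.inact_v_half_mv) * nav.inact_z / rt_f))
    n = 1.0 / (1.0 + math.exp(-(v - kdr.v_half_mv) * kdr.z / rt_f))
    return m, h, n


def _ionic_current(params: NeuronModelParams, v: float, m: float, h: float,
                   n: float, na_mm: float, gkna_eff: float | None = None) -> float:
    nav, kdr, leak, kna = (params.fast_nav, params.delayed_rectifier_k,
                           params.passive_leak, params.kna)
    g_kna = kna.gmax_wholecell_ns if gkna_eff is None else gkna_eff
    po = hill_open_probability(na_mm, kna.na_ec50_mm, kna.na_hill)
    return (nav.gmax_ns * m ** nav.act_power * h * (v - nav.e_rev_mv)
            + kdr.gmax_ns * n ** kdr.act_power * (v - kdr.e_rev_mv)
            + g_kna * po * (v - kna.e_k_mv)
            + leak.g_ns * (v - leak.e_rev_mv))


def holding_state(params: NeuronModelParams, v_hold: float):
    """Steady state at a clamped voltage: gating variables at their
    steady-state values, shell Na at its influx/extrusion balance, and the
    bias current (pA) required to hold the cell there in current clamp."""
    nah = params.na_handling
    m, h, n = _steady_gates(params, v_hold)
    ina = params.fast_nav.gmax_ns * m ** params.fast_nav.act_power * h * \
        (v_hold - params.fast_nav.e_rev_mv)
    influx = max(-ina, 0.0)
    na = nah.resting_na_mm + nah.extrusion_tau_ms * influx * _na_coef(params)
    bias = _ionic_current(params, v_hold, m, h, n, na)
    return (v_hold, m, h, n, na), bias


def resting_potential(params: NeuronModelParams, settle_ms: float = 1000.0) -> float:
    """Free (zero injected current) resting potential, by relaxation from the
    leak reversal potential."""
    v0 = params.passive_leak.e_rev_mv
    m, h, n = _steady_gates(params, v0)
    dt = params.dt_ms
    nsamp = int(round(settle_ms / dt)) + 1
    i_inj = np.zeros(nsamp)
    kna = params.kna
    v, _, fail = _kernels.integrate_cc(
        i_inj, 1, dt, **_gate_args(params, dt),
        gkna=kna.gmax_wholecell_ns, ekna=kna.e_k_mv,
        ec50=kna.na_ec50_mm, hillc=kna.na_hill,
        akna=_kna_alpha(params, dt),
        na_coef=_na_coef(params), ext_tau=params.na_handling.extrusion_tau_ms,
        rest_na=params.na_handling.resting_na_mm,
        v0=v0, m0=m, h0=h, n0=n, na0=params.na_handling.resting_na_mm,
        p0=hill_open_probability(params.na_handling.resting_na_mm,
                                 kna.na_ec50_mm, kna.na_hill))
    if fail >= 0:
        raise IntegrationError(f"integration diverged at t = {fail * dt:.3f} ms")
    return float(v[-1])


# ---------------------------------------------------------------------------
# simulators
# ---------------------------------------------------------------------------

def _infer_genotype(params: NeuronModelParams) -> str:
    return "dKO" if params.kna.gmax_wholecell_ns == 0 else "WT"


def simulate_current_clamp(params: NeuronModelParams, protocol: ProtocolSpec,
                           seed: int = 0, bias_to_holding: bool = True,
                           cell_id: str = "cc-sim",
                           genotype: str | None = None) -> CellRecord:
    """Simulate one current-clamp protocol family.

    With ``bias_to_holding`` the cell is held at ``protocol.holding`` (mV)
    by a constant bias current before and during the sweep, mirroring the
    experimental adjustment of the membrane potential; otherwise the cell
    starts from its free resting state and the command is injected on top of
    zero bias.
    """
    if protocol.mode != "current_clamp":
        raise ValueError("protocol is not a current-clamp protocol")
    dt = params.dt_ms
    n_sub = max(1, int(round(protocol.sample_interval_ms / dt)))
    if abs(n_sub * dt - protocol.sample_interval_ms) > 1e-9:
        raise ValueError("integration step must divide the sample interval")

    if bias_to_holding:
        (v0, m0, h0, n0, na0), bias = holding_state(params, protocol.holding)
    else:
        v0 = resting_potential(params)
        m0, h0, n0 = _steady_gates(params, v0)
        (_, _, _, _, na0), _ = holding_state(params, v0)
        bias = 0.0

    kna = params.kna
    kw = dict(**_gate_args(params, dt),
              gkna=kna.gmax_wholecell_ns, ekna=kna.e_k_mv,
              ec50=kna.na_ec50_mm, hillc=kna.na_hill,
              akna=_kna_alpha(params, dt),
              na_coef=_na_coef(params),
              ext_tau=params.na_handling.extrusion_tau_ms,
              rest_na=params.na_handling.resting_na_mm)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sweeps = []
    for level in protocol.levels:
        t, cmd = protocol.command_waveform(level)
        v, _, fail = _kernels.integrate_cc(
            cmd + bias, n_sub, dt, v0=v0, m0=m0, h0=h0, n0=n0, na0=na0,
            p0=hill_open_probability(na0, kna.na_ec50_mm, kna.na_hill), **kw)
        if fail >= 0:
            raise IntegrationError(
                f"integration diverged at t = {t[min(fail, len(t) - 1)]:.3f} ms "
                f"(level {level} pA)")
        rec = v if params.noise_sd_mv == 0 else \
            v + rng.normal(0.0, params.noise_sd_mv, v.shape)
        sweeps.append(Sweep(t, rec, cmd, mode="current_clamp", level=level))

    record = CellRecord(
        cell_id=cell_id, genotype=genotype or _infer_genotype(params),
        pipette_na_mm=params.na_handling.resting_na_mm,
        capacitance_pf=params.membrane_capacitance_pf, params=params)
    record.add_sweeps("stim", protocol, sweeps)
    return record


def simulate_voltage_clamp(params: NeuronModelParams, protocol: ProtocolSpec,
                           pipette_na_mm: float,
                           times_since_breakin_s=(180.0,),
                           bath: str = "control", seed: int = 0,
                           cell_id: str = "vc-sim",
                           genotype: str | None = None,
                           tau_clamp_ms: float = 0.1) -> CellRecord:
    """Simulate a voltage-clamp protocol at one or more times after break-in.

    The KNa conductance is scaled by the dialysis factor D(t); 20 mM bath Cs
    (``bath="Cs20mM"``) blocks the K currents with the voltage-dependent
    fraction of :data:`CS_BLOCK_REFERENCE`.
    """
    if protocol.mode != "voltage_clamp":
        raise ValueError("protocol is not a voltage-clamp protocol")
    if pipette_na_mm < 0:
        raise ValueError("pipette Na concentration must be non-negative")
    if bath not in ("control", "Cs20mM"):
        raise ValueError(f"unknown bath condition {bath!r}")
    dt = params.dt_ms
    n_sub = max(1, int(round(protocol.sample_interval_ms / dt)))

    kna = params.kna
    cs_on = bath == "Cs20mM"
    blk = CS_BLOCK_REFERENCE
    cs_slope = rt_over_f(params.temperature_c) / blk.z

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sweeps = []
    for t_b in times_since_breakin_s:
        gkna_eff = kna.gmax_wholecell_ns * dialysis_factor(t_b, params)
        v0 = protocol.holding
        m0, h0, n0 = _steady_gates(params, v0)
        for level in protocol.levels:
            t, cmd = protocol.command_waveform(level)
            i, _, fail = _kernels.integrate_vc(
                cmd, n_sub, dt, tau_clamp_ms, **_gate_args(params, dt),
                gkna_eff=gkna_eff, ekna=kna.e_k_mv,
                ec50=kna.na_ec50_mm, hillc=kna.na_hill,
                akna=_kna_alpha(params, dt),
                na_coef=_na_coef(params),
                ext_tau=params.na_handling.extrusion_tau_ms,
                na_eq=pipette_na_mm, cs_on=cs_on, cs_a=blk.a,
                cs_vh=blk.v_half_mv, cs_slope=cs_slope,
                v0=v0, m0=m0, h0=h0, n0=n0, na0=pipette_na_mm,
                p0=hill_open_probability(pipette_na_mm, kna.na_ec50_mm,
                                         kna.na_hill))
            if fail >= 0:
                raise IntegrationError(
                    f"integration diverged at t = {t[min(fail, len(t) - 1)]:.3f} ms")
            rec = i if params.noise_sd_pa == 0 else \
                i + rng.normal(0.0, params.noise_sd_pa, i.shape)
            sweeps.append(Sweep(t, rec, cmd, mode="voltage_clamp",
                                time_since_breakin_s=t_b, bath=bath,
                                level=level))

    record = CellRecord(
        cell_id=cell_id, genotype=genotype or _infer_genotype(params),
        pipette_na_mm=pipette_na_mm,
        capacitance_pf=params.membrane_capacitance_pf, params=params)
    record.add_sweeps("stim", protocol, sweeps)
    return record


def simulate_single_channel(params: NeuronModelParams, voltage_mv: float,
                            duration_ms: float, bath_na_mm: float,
                            seed: int = 0, sample_interval_ms: float = 0.1,
                            noise_sd_pa: float = 0.8,
                            mean_open_ms: float = 4.0,
                            e_k_mv: float = INSIDE_OUT_EK_MV) -> SingleChannelRecord:
    """Two-state Markov gating of a single KNa channel in an inside-out patch.

    Open probability is the Hill function of the bath (cytosolic-face) Na;
    open-level current is unitary conductance times driving force relative to
    the inside-out E_K. Sampling is a point sample of the continuous-time
    process, so the empirical open fraction is unbiased.
    """
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    kna = params.kna
    po = hill_open_probability(bath_na_mm, kna.na_ec50_mm, kna.na_hill)
    if kna.voltage_dependent:
        # weak intrinsic voltage dependence (z ~ 0.1e), anchored at -60 mV
        rt_f = rt_over_f(params.temperature_c)
        po = min(1.0, po * math.exp(0.1 * (voltage_mv + 60.0) / rt_f))
    n = int(round(duration_ms / sample_interval_ms)) + 1
    t = np.arange(n) * sample_interval_ms
    amp = kna.unitary_conductance_ps * 1e-3 * (voltage_mv - e_k_mv)

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if po <= 0.0:
        state = np.zeros(n)
    elif po >= 1.0:
        state = np.ones(n)
    else:
        mean_closed = mean_open_ms * (1.0 - po) / po
        # alternating dwell times; start state from the stationary law
        n_dwell = int(duration_ms / (mean_open_ms + mean_closed) * 3) + 64
        start_open = rng.random() < po
        means = np.empty(2 * n_dwell)
        means[0::2] = mean_open_ms if start_open else mean_closed
        means[1::2] = mean_closed if start_open else mean_open_ms
        edges = np.cumsum(rng.exponential(means))
        while edges[-1] < duration_ms:  # pragma: no cover - generous sizing
            extra = np.cumsum(rng.exponential(means)) + edges[-1]
            edges = np.concatenate([edges, extra])
        idx = np.searchsorted(edges, t, side="right")
        open_parity = 0 if start_open else 1
        state = (idx % 2 == open_parity).astype(float)

    current = state * amp + rng.normal(0.0, noise_sd_pa, n)
    return SingleChannelRecord(holding_mv=voltage_mv, time_ms=t,
                               current_pa=current, true_open_probability=po,
                               bath_na_mm=bath_na_mm, e_k_mv=e_k_mv)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: parameters perturbed across cells of a cohort (attribute paths)
_COHORT_VARIED = (
    ("membrane_capacitance_pf",),
    ("fast_nav", "gmax_ns"),
    ("delayed_rectifier_k", "gmax_ns"),
    ("passive_leak", "g_ns"),
    ("kna", "gmax_wholecell_ns"),
)


def _perturb(params: NeuronModelParams, variability: float,
             rng: np.random.Generator) -> NeuronModelParams:
    p = params.copy()
    if variability <= 0:
        return p
    sigma = math.sqrt(math.log(1.0 + variability ** 2))
    for path in _COHORT_VARIED:
        obj = p
        for attr in path[:-1]:
            obj = getattr(obj, attr)
        base = getattr(obj, path[-1])
        # the draw is consumed unconditionally so cohorts generated from the
        # same seed are matched cell by cell across genotypes
        factor = rng.lognormal(-0.5 * sigma ** 2, sigma)
        if base > 0:
            # mean-preserving log-normal: E[value] = base, CV ~ variability
            setattr(obj, path[-1], base * factor)
    return p


def make_cohort(n_cells: int, genotype: str = "WT",
                pipette_na_mm: float = 10.0, variability: float = 0.2,
                seed: int = 0, template: NeuronModelParams | None = None,
                protocols: dict | None = None,
                times_since_breakin_s=(180.0,)) -> list:
    """Draw a cohort of cells with log-normally perturbed parameters.

    Each cell gets an independent substream of the seeded generator, so the
    cohort is reproducible and insensitive to the order of simulation. If
    ``protocols`` (name -> :class:`ProtocolSpec`) is given, each protocol is
    simulated and attached to the cell record.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be at least 1")
    if variability < 0:
        raise ValueError("variability must be non-negative")
    base = (template or template_params(genotype)).copy()
    if genotype in KNA_NULL_GENOTYPES:
        base.kna.gmax_wholecell_ns = 0.0
    base.na_handling.resting_na_mm = pipette_na_mm

    children = np.random.SeedSequence(seed).spawn(n_cells)
    cells = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        p = _perturb(base, variability, rng)
        sim_seed = int(child.generate_state(1)[0] % (2 ** 31))
        record = CellRecord(
            cell_id=f"{genotype}-{pipette_na_mm:g}Na-{i:03d}",
            genotype=genotype, pipette_na_mm=pipette_na_mm,
            capacitance_pf=p.membrane_capacitance_pf, params=p)
        if protocols:
            for name, proto in protocols.items():
                if proto.mode == "current_clamp":
                    rec = simulate_current_clamp(p, proto, seed=sim_seed)
                else:
                    rec = simulate_voltage_clamp(
                        p, proto, pipette_na_mm,
                        times_since_breakin_s=times_since_breakin_s,
                        seed=sim_seed)
                record.add_sweeps(name, proto, rec.sweeps["stim"])
                sim_seed = (sim_seed + 1) % (2 ** 31)
        cells.append(record)
    return cells
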