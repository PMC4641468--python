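"""Core domain types: model parameters, stimulation protocols, recordings.

The types mirror what a patch-clamp rig produces: a :class:`Sweep` is one
stimulus/response pair, a :class:`CellRecord` collects the sweeps of one cell
together with its genotype and pipette solution, and
:class:`NeuronModelParams` holds every knob of the conductance-based model
used to generate synthetic recordings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import Optional

import numpy as np

from .constants import DEFAULT_TEMPERATURE_C

GENOTYPES = ("WT", "Slo2.1KO", "Slo2.2KO", "dKO")
#: genotypes whose DRG neurons lack the Slo2.2-encoded KNa current
KNA_NULL_GENOTYPES = ("Slo2.2KO", "dKO")


# ---------------------------------------------------------------------------
# model parameters
# ---------------------------------------------------------------------------

@dataclass
class NavParams:
    """Transient voltage-gated Na conductance (single HH-type population).

    Each activation gate is a Boltzmann with midpoint ``v_half`` (mV) and
    effective gating charge ``z`` (elementary charges), raised to
    ``act_power``; with the default m^3 gate (v_half -20 mV, z 3.3e) the
    whole-cell conductance activation curve has a midpoint near -10 mV and an
    effective charge near 4.1e, the values measured for the peak inward
    current of these neurons. Inactivation is a single Boltzmann gate with a
    bell-shaped voltage-dependent time constant: slow in the subthreshold
    window, fast both during the spike and at recovery potentials.
    """

    gmax_ns: float = 600.0
    e_rev_mv: float = 60.0
    v_half_mv: float = -20.0
    z: float = 3.3
    act_power: int = 3
    tau_act_ms: float = 0.2
    inact_v_half_mv: float = -35.0
    inact_z: float = 3.0
    tau_inact_min_ms: float = 1.0
    tau_inact_amp_ms: float = 100.0
    tau_inact_v_half_mv: float = -35.0
    tau_inact_k_mv: float = 8.0


@dataclass
class KdrParams:
    """Delayed-rectifier K conductance (single Boltzmann-activated gate)."""

    gmax_ns: float = 50.0
    e_rev_mv: float = -80.0
    v_half_mv: float = -15.0
    z: float = 3.5
    act_power: int = 1
    tau_act_ms: float = 4.0


@dataclass
class LeakParams:
    """Ohmic passive leak."""

    g_ns: float = 1.0
    e_rev_mv: float = -52.0


@dataclass
class KnaParams:
    """Na-activated K conductance (Slo2.2 / Slack).

    Open probability follows a Hill function of submembrane [Na+] with a
    short first-order activation lag (``activation_tau_ms``; set it to 0 for
    strictly instantaneous coupling). The channel itself is treated as
    voltage independent over the physiological range (weak intrinsic voltage
    dependence).
    """

    gmax_wholecell_ns: float = 69.0
    unitary_conductance_ps: float = 127.0
    e_k_mv: float = -80.0
    na_ec50_mm: float = 40.0
    na_hill: float = 3.5
    activation_tau_ms: float = 4.0
    voltage_dependent: bool = False


@dataclass
class NaHandling:
    """Submembrane Na accounting: a thin shell filled by Nav influx and
    cleared first order toward the pipette-set resting level."""

    shell_volume_pl: float = 0.0015
    extrusion_tau_ms: float = 25.0
    resting_na_mm: float = 10.0


@dataclass
class DialysisParams:
    """Whole-cell dialysis of pipette Na and slow rundown of the KNa
    conductance, both in seconds."""

    equilibration_tau_s: float = 60.0
    rundown_tau_s: float = 900.0


@dataclass
class NeuronModelParams:
    """Full parameter set of the single-compartment DRG neuron model."""

    membrane_capacitance_pf: float = 16.1
    fast_nav: NavParams = field(default_factory=NavParams)
    delayed_rectifier_k: KdrParams = field(default_factory=KdrParams)
    passive_leak: LeakParams = field(default_factory=LeakParams)
    kna: KnaParams = field(default_factory=KnaParams)
    na_handling: NaHandling = field(default_factory=NaHandling)
    dialysis: DialysisParams = field(default_factory=DialysisParams)
    noise_sd_mv: float = 0.3
    noise_sd_pa: float = 5.0
    temperature_c: float = DEFAULT_TEMPERATURE_C
    dt_ms: float = 0.01

    def __post_init__(self) -> None:
        for g in (self.fast_nav.gmax_ns, self.delayed_rectifier_k.gmax_ns,
                  self.passive_leak.g_ns, self.kna.gmax_wholecell_ns):
            if g < 0:
                raise ValueError("conductances must be non-negative")
        if self.kna.na_ec50_mm <= 0:
            raise ValueError("na_ec50 must be positive")
        if not self.dialysis.equilibration_tau_s < self.dialysis.rundown_tau_s:
            raise ValueError("dialysis equilibration tau must be shorter than "
                             "rundown tau")
        if self.dt_ms <= 0:
            raise ValueError("integration step must be positive")

    def copy(self) -> "NeuronModelParams":
        return NeuronModelParams(
            membrane_capacitance_pf=self.membrane_capacitance_pf,
            fast_nav=replace(self.fast_nav),
            delayed_rectifier_k=replace(self.delayed_rectifier_k),
            passive_leak=replace(self.passive_leak),
            kna=replace(self.kna),
            na_handling=replace(self.na_handling),
            dialysis=replace(self.dialysis),
            noise_sd_mv=self.noise_sd_mv,
            noise_sd_pa=self.noise_sd_pa,
            temperature_c=self.temperature_c,
            dt_ms=self.dt_ms,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NeuronModelParams":
        d = dict(d)
        return cls(
            membrane_capacitance_pf=d["membrane_capacitance_pf"],
            fast_nav=NavParams(**d["fast_nav"]),
            delayed_rectifier_k=KdrParams(**d["delayed_rectifier_k"]),
            passive_leak=LeakParams(**d["passive_leak"]),
            kna=KnaParams(**d["kna"]),
            na_handling=NaHandling(**d["na_handling"]),
            dialysis=DialysisParams(**d["dialysis"]),
            noise_sd_mv=d["noise_sd_mv"],
            noise_sd_pa=d["noise_sd_pa"],
            temperature_c=d["temperature_c"],
            dt_ms=d["dt_ms"],
        )


def template_params(genotype: str = "WT") -> NeuronModelParams:
    """Default model parameters for a genotype.

    Slo2.2-null genotypes (``Slo2.2KO`` and ``dKO``) have no KNa current;
    ``Slo2.1KO`` neurons are indistinguishable from WT in this respect.
    """
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}; expected one of {GENOTYPES}")
    p = NeuronModelParams()
    if genotype in KNA_NULL_GENOTYPES:
        p.kna.gmax_wholecell_ns = 0.0
    return p


# ---------------------------------------------------------------------------
# protocols
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProtocolSpec:
    """A stimulation protocol: a family of sweeps sharing one waveform shape.

    Parameters
    ----------
    kind : {"step", "ramp", "pulse_train"}
    mode : {"current_clamp", "voltage_clamp"}
    holding : float
        In voltage clamp, the holding potential (mV). In current clamp, the
        *target* holding voltage (mV): the simulator applies the bias current
        that holds the cell there, mirroring the experimental practice of
        adjusting the membrane potential before stimulation.
    levels : tuple of float
        One sweep per level. For steps this is the step level (mV in voltage
        clamp) or the injected current amplitude (pA in current clamp); for
        ramps it is the ramp end voltage; for pulse trains the pulse amplitude.
    """

    kind: str
    mode: str
    holding: float
    levels: tuple
    duration_ms: float
    pre_ms: float = 20.0
    post_ms: float = 50.0
    sample_interval_ms: float = 0.05
    n_pulses: int = 1
    pulse_freq_hz: float = 7.1
    pulse_width_ms: float = 10.0
    inter_sweep_interval_s: float = 5.0

    def __post_init__(self) -> None:
        if self.kind not in ("step", "ramp", "pulse_train"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.mode not in ("current_clamp", "voltage_clamp"):
            raise ValueError(f"unknown clamp mode {self.mode!r}")
        if self.duration_ms <= 0 or self.pre_ms < 0 or self.post_ms < 0:
            raise ValueError("durations must be positive")
        if self.sample_interval_ms <= 0:
            raise ValueError("sample interval must be positive")
        for seg in (self.duration_ms, self.pre_ms, self.post_ms):
            n = seg / self.sample_interval_ms
            if abs(n - round(n)) > 1e-9 * max(1.0, n):
                raise ValueError("sample interval must divide segment durations")

    @property
    def total_ms(self) -> float:
        if self.kind == "pulse_train" and self.n_pulses > 0:
            period = 1000.0 / self.pulse_freq_hz
            train = (self.n_pulses - 1) * period + self.pulse_width_ms
            return self.pre_ms + train + self.post_ms
        return self.pre_ms + self.duration_ms + self.post_ms

    def command_waveform(self, level: float) -> tuple:
        """Return (time_ms, command) arrays for one sweep at ``level``.

        In current clamp the command is the injected current relative to the
        bias holding current (pA); in voltage clamp it is the absolute command
        voltage (mV).
        """
        dt = self.sample_interval_ms
        n = int(round(self.total_ms / dt)) + 1
        t = np.arange(n) * dt
        if self.mode == "voltage_clamp":
            base = self.holding
        else:
            base = 0.0
        cmd = np.full(n, float(base))
        if self.kind == "step":
            i0 = int(round(self.pre_ms / dt))
            i1 = int(round((self.pre_ms + self.duration_ms) / dt))
            cmd[i0:i1] = level
        elif self.kind == "ramp":
            i0 = int(round(self.pre_ms / dt))
            i1 = int(round((self.pre_ms + self.duration_ms) / dt))
            start = self.holding if self.mode == "voltage_clamp" else 0.0
            cmd[i0:i1] = np.linspace(start, level, i1 - i0, endpoint=False)
        else:  # pulse_train
            period = 1000.0 / self.pulse_freq_hz
            for k in range(self.n_pulses):
                p0 = self.pre_ms + k * period
                i0 = int(round(p0 / dt))
                i1 = int(round((p0 + self.pulse_width_ms) / dt))
                cmd[i0:i1] = level
        return t, cmd


def standard_protocols() -> dict:
    """The standard stimulation protocols of the analysis chain, by name."""
    return {
        # hyperpolarizing step for Na-dependent background (leak) current
        "leak_step": ProtocolSpec(
            kind="step", mode="voltage_clamp", holding=-80.0,
            levels=(-120.0,), duration_ms=100.0, pre_ms=50.0, post_ms=50.0),
        # steady-state I-V family
        "iv_steps": ProtocolSpec(
            kind="step", mode="voltage_clamp", holding=-80.0,
            levels=tuple(np.arange(-125.0, -24.0, 10.0)),
            duration_ms=20.0, pre_ms=20.0, post_ms=20.0),
        # 1 s current steps for f-I analysis
        "fi_steps": ProtocolSpec(
            kind="step", mode="current_clamp", holding=-60.0,
            levels=(40.0, 60.0, 100.0, 200.0), duration_ms=1000.0,
            pre_ms=100.0, post_ms=200.0),
        # 20 ms current steps for rheobase
        "rheobase_steps": ProtocolSpec(
            kind="step", mode="current_clamp", holding=-60.0,
            levels=tuple(np.arange(20.0, 301.0, 10.0)), duration_ms=20.0,
            pre_ms=20.0, post_ms=80.0),
        # 40 ms depolarizing voltage ramp (to -5 mV; a -20 mV variant is
        # obtained by passing levels=(-20,))
        "ramp": ProtocolSpec(
            kind="ramp", mode="voltage_clamp", holding=-60.0,
            levels=(-5.0,), duration_ms=40.0, pre_ms=20.0, post_ms=20.0),
        # input resistance: 10 mV hyperpolarizing step
        "rin_step": ProtocolSpec(
            kind="step", mode="voltage_clamp", holding=-60.0,
            levels=(-70.0,), duration_ms=100.0, pre_ms=50.0, post_ms=50.0),
        # AP trains for slow-AHP assessment (7.1 Hz)
        "ahp_train": ProtocolSpec(
            kind="pulse_train", mode="current_clamp", holding=-60.0,
            levels=(200.0,), duration_ms=10.0, pre_ms=100.0, post_ms=1500.0,
            n_pulses=1, pulse_freq_hz=7.1, pulse_width_ms=10.0),
    }


# ---------------------------------------------------------------------------
# recordings
# ---------------------------------------------------------------------------

@dataclass
class Sweep:
    """One recorded sweep: uniform time base, recorded signal, command."""

    time_ms: np.ndarray
    recorded: np.ndarray
    command: np.ndarray
    mode: str = "current_clamp"
    time_since_breakin_s: float = 180.0
    bath: str = "control"
    level: Optional[float] = None

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.recorded = np.asarray(self.recorded, dtype=float)
        self.command = np.asarray(self.command, dtype=float)
        if not (len(self.time_ms) == len(self.recorded) == len(self.command)):
            raise ValueError("time, recorded and command must have equal length")
        if len(self.time_ms) >= 2:
            dts = np.diff(self.time_ms)
            if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
                raise ValueError("non-uniform time base")

    @property
    def dt_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0])


@dataclass
class CellRecord:
    """All sweeps of one cell, grouped by protocol name."""

    cell_id: str
    genotype: str
    pipette_na_mm: float
    capacitance_pf: float
    ib4_positive: bool = True
    protocols: dict = field(default_factory=dict)
    sweeps: dict = field(default_factory=dict)
    params: Optional[NeuronModelParams] = None

    def __post_init__(self) -> None:
        if self.pipette_na_mm < 0:
            raise ValueError("pipette Na concentration must be non-negative")
        for name in self.sweeps:
            if name not in self.protocols:
                raise ValueError(f"sweep group {name!r} references no protocol "
                                 "in this record")

    def add_sweeps(self, name: str, protocol: ProtocolSpec, sweeps: list) -> None:
        self.protocols[name] = protocol
        self.sweeps.setdefault(name, []).extend(sweeps)


@dataclass
class SingleChannelRecord:
    """An excised inside-out patch record with (close to) one active channel."""

    holding_mv: float
    time_ms: np.ndarray
    current_pa: np.ndarray
    true_open_probability: float
    bath_na_mm: float
    e_k_mv: float = 18.35

    @property
    def dt_ms(self) -> float:
        return float(self.time_ms[1] - self.time_ms[0])


# ---------------------------------------------------------------------------
# fit results
# ---------------------------------------------------------------------------

@dataclass
class BlockFit:
    """Voltage-dependent fractional block of KNa current by extracellular Cs.

    f(V) = 1 - A / (1 + exp(-zF(V - V_h)/RT)): complete block at very negative
    voltages relaxing to a voltage-independent floor of 1 - A at positive
    voltages.
    """

    a: float
    v_half_mv: float
    z: float
    temperature_c: float = DEFAULT_TEMPERATURE_C
    residual_norm: float = 0.0
    covariance: Optional[np.ndarray] = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.a <= 1.0):
            raise ValueError("block amplitude A must lie in [0, 1]")
        if self.z < 0:
            raise ValueError("gating charge must be non-negative")


@dataclass
class BoltzmannFit:
    """Boltzmann chord-conductance activation fit g(V) = gmax/(1+exp(...))."""

    g_max_ns: float
    v_half_mv: float
    z: float
    reversal_mv: float = 75.0
    temperature_c: float = DEFAULT_TEMPERATURE_C
    residual_norm: float = 0.0
    covariance: Optional[np.ndarray] = None
    steep_flag: bool = False

    def __post_init__(self) -> None:
        if self.g_max_ns <= 0:
            raise ValueError("g_max must be positive")
        if self.z <= 0:
            raise ValueError("gating charge must be positive")


@dataclass
class ChordModel:
    """Chord-conductance membrane-potential model.

    ``branches`` is a list of (label, conductance nS, reversal mV); an
    optional KNa conductance (reversal ``e_k_mv``) is tracked separately so
    it can be swept.
    """

    branches: list = field(default_factory=lambda: [
        ("K", 0.7, -80.0),
        ("Na", 0.165, 60.0),
        ("Cl", 0.3, -50.0),
    ])
    g_kna_ns: float = 0.0
    e_k_mv: float = -80.0

    def __post_init__(self) -> None:
        if self.g_kna_ns < 0:
            raise ValueError("KNa conductance must be non-negative")
        if self.total_conductance_ns() <= 0:
            raise ValueError("total conductance must be positive")

    def all_branches(self) -> list:
        out = list(self.branches)
        if self.g_kna_ns > 0:
            out.append(("KNa", self.g_kna_ns, self.e_k_mv))
        return out

    def total_conductance_ns(self) -> float:
        return sum(g for _, g, _ in self.branches) + self.g_kna_ns

    def with_kna(self, g_kna_ns: float) -> "ChordModel":
        return ChordModel(branches=list(self.branches), g_kna_ns=g_kna_ns,
                          e_k_mv=self.e_k_mv)
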