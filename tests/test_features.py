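"""AP feature extraction: constructed-waveform oracles and model orderings."""

import math

import numpy as np
import pytest

from kna_ephys.datatypes import CellRecord, ProtocolSpec, Sweep
from kna_ephys.features import (
    NoAPError,
    NoCrossingError,
    UnboundedRheobaseError,
    ap_shape_features,
    ap_threshold,
    detect_aps,
    fi_curve,
    input_resistance,
    ramp_zero_crossing,
    rheobase,
    rheobase_bisect,
    train_ahp,
)
from kna_ephys.simulate import simulate_current_clamp, simulate_voltage_clamp

DT = 0.05


def cc_sweep(v, level=None):
    v = np.asarray(v, dtype=float)
    t = np.arange(len(v)) * DT
    return Sweep(t, v, np.zeros_like(v), mode="current_clamp", level=level)


def stereotyped_spike(dt=DT, width_ms=2.0, peak=30.0, base=-60.0):
    """Triangular spike rising over width/2 and falling over width/2."""
    n_half = int(width_ms / 2 / dt)
    up = np.linspace(base, peak, n_half, endpoint=False)
    down = np.linspace(peak, base, n_half + 1)
    return np.concatenate([up, down])


def spike_train_trace(n_spikes, isi_ms=50.0, dt=DT):
    base = -60.0
    spike = stereotyped_spike(dt)
    n_isi = int(isi_ms / dt)
    v = [np.full(n_isi, base)]
    positions = []
    for _ in range(n_spikes):
        positions.append(sum(len(seg) for seg in v) + len(spike) // 2)
        v.append(spike)
        v.append(np.full(n_isi, base))
    return np.concatenate(v), positions


class TestDetectAps:
    def test_flat_trace_has_no_events(self):
        assert detect_aps(cc_sweep(np.full(4000, -60.0))) == []

    def test_stereotyped_train_counted_exactly(self):
        v, positions = spike_train_trace(10)
        events = detect_aps(cc_sweep(v))
        assert len(events) == 10
        for ev, pos in zip(events, positions):
            assert abs(ev.peak_time_ms - pos * DT) <= DT

    def test_count_matches_zero_crossing_oracle(self, wt_params):
        proto = ProtocolSpec(kind="step", mode="current_clamp", holding=-60.0,
                             levels=(200.0,), duration_ms=1000.0,
                             pre_ms=100.0, post_ms=100.0)
        s = simulate_current_clamp(wt_params, proto, seed=3).sweeps["stim"][0]
        v = s.recorded
        oracle = int(np.sum((v[:-1] < 0.0) & (v[1:] >= 0.0)))
        assert len(detect_aps(s)) == oracle

    def test_slow_depolarization_not_counted(self):
        # crosses 0 mV but with dV/dt far below the 10 mV/ms criterion
        t = np.arange(0, 400, DT)
        v = -60.0 + 70.0 * t / t[-1]  # 0.175 mV/ms
        assert detect_aps(cc_sweep(v)) == []

    def test_requires_current_clamp(self):
        s = Sweep(np.arange(3) * DT, np.zeros(3), np.zeros(3),
                  mode="voltage_clamp")
        with pytest.raises(ValueError):
            detect_aps(s)


def logistic_upstroke(amp=110.0, tau=0.5, base=-80.0, dt=0.01):
    """Logistic spike upstroke V(t) = base + amp*s(t), s the sigmoid.

    dV/dt = amp*s(1-s)/tau peaks at the midpoint; the crossing of a fraction
    f of that peak sits at s = (1 - sqrt(1-f))/2, so the 10% threshold and
    the fraction-1 potential (base + amp/2) are both in closed form.
    """
    t0 = 20.0
    t = np.arange(0.0, 40.0, dt)
    s = 1.0 / (1.0 + np.exp(-(t - t0) / tau))
    v = base + amp * s
    down = np.linspace(v[-1], base, int(5.0 / dt))
    vv = np.concatenate([v, down])
    sweep = Sweep(np.arange(len(vv)) * dt, vv, np.zeros_like(vv),
                  mode="current_clamp")
    s10 = (1.0 - math.sqrt(1.0 - 0.10)) / 2.0
    return sweep, base + amp * s10, base + amp / 2.0


class TestApThreshold:
    def test_analytic_logistic_upstroke(self):
        sweep, expected, _ = logistic_upstroke()
        assert ap_threshold(sweep) == pytest.approx(expected, abs=0.2)

    def test_fraction_one_returns_potential_at_peak_dvdt(self):
        sweep, _, midpoint = logistic_upstroke()
        got = ap_threshold(sweep, fraction=1.0)
        assert got == pytest.approx(midpoint, abs=0.5)

    def test_threshold_shifts_with_constant_offset(self):
        sweep, _, _ = logistic_upstroke()
        shifted = Sweep(sweep.time_ms, sweep.recorded + 7.5, sweep.command,
                        mode="current_clamp")
        assert ap_threshold(shifted) == pytest.approx(
            ap_threshold(sweep) + 7.5, abs=1e-9)

    def test_kna_null_threshold_more_negative_than_wt(self, wt_params,
                                                      dko_params,
                                                      single_ap_step):
        wt = simulate_current_clamp(wt_params, single_ap_step, seed=2)
        ko = simulate_current_clamp(dko_params, single_ap_step, seed=2)
        t_wt = ap_threshold(wt.sweeps["stim"][0])
        t_ko = ap_threshold(ko.sweeps["stim"][0])
        assert t_ko < t_wt

    def test_no_ap_raises(self):
        with pytest.raises(NoAPError):
            ap_threshold(cc_sweep(np.full(2000, -60.0)))

    def test_invalid_fraction_rejected(self):
        sweep, _, _ = logistic_upstroke()
        with pytest.raises(ValueError):
            ap_threshold(sweep, fraction=0.0)


class TestApShape:
    def test_triangular_spike_half_width(self):
        # symmetric triangle with 4 ms base: half-width = 2 ms
        v = np.concatenate([np.full(1000, -60.0),
                            stereotyped_spike(width_ms=4.0),
                            np.full(1000, -60.0)])
        ev = ap_shape_features(cc_sweep(v))
        assert ev.half_width_ms == pytest.approx(2.0, abs=0.15)
        assert ev.peak_v_mv == pytest.approx(30.0, abs=0.5)

    def test_constructed_half_amplitude_crossings(self):
        # trapezoid whose half-amplitude crossings are known exactly
        dt = DT
        base, peak = -60.0, 20.0
        up = np.linspace(base, peak, int(1.0 / dt), endpoint=False)
        plateau = np.full(int(2.0 / dt), peak)
        down = np.linspace(peak, base, int(1.0 / dt))
        v = np.concatenate([np.full(400, base), up, plateau, down,
                            np.full(1000, base)])
        ev = ap_shape_features(cc_sweep(v))
        # threshold ~ base; half level ~ -20: crossings at 0.5 ms into the
        # rise and 0.5 ms into the fall -> width = 0.5 + 2.0 + 0.5
        assert ev.half_width_ms == pytest.approx(3.0, abs=0.2)

    def test_ahp_is_post_spike_minimum(self):
        v, _ = spike_train_trace(1)
        ipk = int(np.argmax(v))
        v[ipk + 200: ipk + 300] = -78.0  # dip 10-15 ms after the peak
        ev = ap_shape_features(cc_sweep(v))
        assert ev.ahp_min_mv == -78.0

    def test_wt_template_ahp_near_minus_74(self, wt_params, single_ap_step):
        rec = simulate_current_clamp(wt_params, single_ap_step, seed=0)
        ev = ap_shape_features(rec.sweeps["stim"][0])
        assert -85.0 < ev.ahp_min_mv < -65.0

    def test_clipped_peak_flagged(self):
        v, _ = spike_train_trace(1)
        ev = ap_shape_features(cc_sweep(v), ceiling_mv=30.0)
        assert ev.clipped


def step_family_record(spiking_levels, levels=(30.0, 60.0, 90.0, 120.0)):
    proto = ProtocolSpec(kind="step", mode="current_clamp", holding=-60.0,
                         levels=levels, duration_ms=20.0, pre_ms=20.0,
                         post_ms=60.0)
    sweeps = []
    for lv in levels:
        if lv in spiking_levels:
            v, _ = spike_train_trace(1)
        else:
            v = np.full(4000, -55.0)
        sweeps.append(cc_sweep(v, level=lv))
    rec = CellRecord(cell_id="x", genotype="WT", pipette_na_mm=10.0,
                     capacitance_pf=16.0)
    rec.add_sweeps("stim", proto, sweeps)
    return rec


class TestRheobase:
    def test_smallest_spiking_level(self):
        rec = step_family_record(spiking_levels={90.0, 120.0})
        assert rheobase(rec) == 90.0

    def test_no_spiking_sweep_raises(self):
        with pytest.raises(UnboundedRheobaseError):
            rheobase(step_family_record(spiking_levels=set()))

    def test_bisection_matches_exhaustive_scan(self, wt_params):
        def spikes_at(amp):
            proto = ProtocolSpec(kind="step", mode="current_clamp",
                                 holding=-60.0, levels=(amp,),
                                 duration_ms=20.0, pre_ms=20.0, post_ms=80.0)
            rec = simulate_current_clamp(wt_params, proto, seed=0)
            return bool(detect_aps(rec.sweeps["stim"][0]))

        lo, hi, inc = 40.0, 100.0, 2.0
        by_bisect = rheobase_bisect(spikes_at, lo, hi, inc)
        exhaustive = next(a for a in np.arange(lo, hi + inc, inc)
                          if spikes_at(a))
        assert by_bisect == exhaustive

    def test_kna_null_rheobase_below_wt(self, wt_params, dko_params):
        proto = ProtocolSpec(kind="step", mode="current_clamp", holding=-60.0,
                             levels=tuple(np.arange(30.0, 121.0, 4.0)),
                             duration_ms=20.0, pre_ms=20.0, post_ms=80.0)
        r = {}
        for name, p in (("WT", wt_params), ("dKO", dko_params)):
            rec = simulate_current_clamp(p, proto, seed=1)
            r[name] = rheobase(rec)
        assert r["dKO"] < r["WT"]

    def test_rheobase_non_increasing_as_kna_decreases(self):
        from kna_ephys.datatypes import template_params
        proto = ProtocolSpec(kind="step", mode="current_clamp", holding=-60.0,
                             levels=tuple(np.arange(30.0, 121.0, 4.0)),
                             duration_ms=20.0, pre_ms=20.0, post_ms=80.0)
        values = []
        for g in (69.0, 30.0, 10.0, 0.0):
            p = template_params("WT")
            p.noise_sd_mv = 0.0
            p.kna.gmax_wholecell_ns = g
            values.append(rheobase(simulate_current_clamp(p, proto, seed=0)))
        assert all(a >= b for a, b in zip(values, values[1:]))


class TestFICurve:
    def test_passive_cell_counts_all_zero(self, wt_params):
        from test_simulate import passive_only
        p = passive_only(wt_params)
        proto = ProtocolSpec(kind="step", mode="current_clamp", holding=-52.0,
                             levels=(40.0, 100.0), duration_ms=500.0)
        rec = simulate_current_clamp(p, proto, seed=0)
        assert fi_curve(rec) == [(40.0, 0), (100.0, 0)]

    def test_counts_match_crossing_oracle_and_orderings(self, wt_params,
                                                        dko_params):
        proto = ProtocolSpec(kind="step", mode="current_clamp", holding=-60.0,
                             levels=(60.0, 100.0, 200.0), duration_ms=1000.0,
                             pre_ms=100.0, post_ms=100.0)
        curves = {}
        for name, p in (("WT", wt_params), ("dKO", dko_params)):
            rec = simulate_current_clamp(p, proto, seed=5)
            curve = fi_curve(rec)
            for (lv, n), s in zip(curve, rec.sweeps["stim"]):
                v = s.recorded
                assert n == int(np.sum((v[:-1] < 0.0) & (v[1:] >= 0.0)))
            counts = [n for _, n in curve]
            assert counts == sorted(counts)  # non-decreasing in current
            curves[name] = counts
        assert all(k >= w for w, k in zip(curves["WT"], curves["dKO"]))


class TestRampZeroCrossing:
    def test_linear_current_crosses_at_reversal(self):
        dt = DT
        n_pre, n_ramp, n_post = int(20 / dt), int(40 / dt), int(20 / dt)
        cmd = np.concatenate([np.full(n_pre, -60.0),
                              np.linspace(-60.0, -5.0, n_ramp,
                                          endpoint=False),
                              np.full(n_post, -5.0)])
        i = 2.0 * (cmd - (-35.0))
        t = np.arange(len(cmd)) * dt
        s = Sweep(t, i, cmd, mode="voltage_clamp")
        assert ramp_zero_crossing(s, smooth_ms=0.0) == pytest.approx(
            -35.0, abs=0.1)

    def test_interpolation_within_one_sample_of_oversampled_oracle(
            self, wt_params, protocols):
        rec = simulate_voltage_clamp(wt_params, protocols["ramp"], 10.0,
                                     (180.0,))
        s = rec.sweeps["stim"][0]
        got = ramp_zero_crossing(s)
        # oracle: same data linearly interpolated onto a 100x finer grid
        fine_t = np.linspace(s.time_ms[0], s.time_ms[-1],
                             (len(s.time_ms) - 1) * 100 + 1)
        fine = Sweep(fine_t, np.interp(fine_t, s.time_ms, s.recorded),
                     np.interp(fine_t, s.time_ms, s.command),
                     mode="voltage_clamp")
        oracle = ramp_zero_crossing(fine)
        ramp_mv_per_sample = 55.0 / 40.0 * s.dt_ms
        assert abs(got - oracle) <= ramp_mv_per_sample

    def test_kna_null_crossing_more_negative(self, wt_params, dko_params,
                                             protocols):
        vals = {}
        for name, p in (("WT", wt_params), ("dKO", dko_params)):
            rec = simulate_voltage_clamp(p, protocols["ramp"], 10.0, (180.0,))
            vals[name] = ramp_zero_crossing(rec.sweeps["stim"][0])
        assert vals["dKO"] < vals["WT"]

    def test_no_crossing_raises(self):
        dt = DT
        n = int(80 / dt)
        cmd = np.linspace(-60.0, -5.0, n)
        i = np.full(n, 50.0)  # purely outward
        s = Sweep(np.arange(n) * dt, i, cmd, mode="voltage_clamp")
        with pytest.raises(NoCrossingError):
            ramp_zero_crossing(s)


class TestInputResistance:
    @staticmethod
    def _vc_record(g_ns):
        proto = ProtocolSpec(kind="step", mode="voltage_clamp", holding=-60.0,
                             levels=(-70.0,), duration_ms=100.0, pre_ms=50.0,
                             post_ms=50.0)
        t, cmd = proto.command_waveform(-70.0)
        i = g_ns * (cmd - (-60.0))
        rec = CellRecord(cell_id="x", genotype="WT", pipette_na_mm=10.0,
                         capacitance_pf=16.0)
        rec.add_sweeps("stim", proto,
                       [Sweep(t, i, cmd, mode="voltage_clamp")])
        return rec

    def test_ohmic_cell_gives_reciprocal_conductance(self):
        # 0.8 nS -> 1250 MOhm
        assert input_resistance(self._vc_record(0.8)) == pytest.approx(1250.0)

    def test_matches_two_point_regression_oracle(self):
        rec = self._vc_record(1.7)
        s = rec.sweeps["stim"][0]
        dt = s.dt_ms
        pts_v = np.array([-60.0, -70.0])
        pts_i = np.array([s.recorded[:int(48 / dt)].mean(),
                          s.recorded[int(100 / dt):int(148 / dt)].mean()])
        slope = np.polyfit(pts_v, pts_i, 1)[0]  # nS
        assert input_resistance(rec) == pytest.approx(1e3 / slope, rel=1e-6)

    def test_wt_template_gigaohm_scale(self, wt_params, protocols):
        rec = simulate_voltage_clamp(wt_params, protocols["rin_step"], 10.0,
                                     (180.0,))
        cell = CellRecord(cell_id="x", genotype="WT", pipette_na_mm=10.0,
                          capacitance_pf=16.0)
        cell.add_sweeps("stim", protocols["rin_step"], rec.sweeps["stim"])
        assert 250.0 < input_resistance(cell) < 3000.0

    def test_noise_floor_flag(self):
        with pytest.raises(ValueError, match="unreliable"):
            input_resistance(self._vc_record(1e-6))


def train_protocol(n_pulses):
    return ProtocolSpec(kind="pulse_train", mode="current_clamp",
                        holding=-60.0, levels=(200.0,), duration_ms=10.0,
                        pre_ms=100.0, post_ms=1200.0, n_pulses=n_pulses,
                        pulse_freq_hz=7.1, pulse_width_ms=10.0)


class TestTrainAhp:
    def test_no_slow_ahp_in_default_model(self, wt_params):
        amps = {}
        for n in (1, 5, 10):
            rec = simulate_current_clamp(wt_params, train_protocol(n), seed=7)
            amps[n] = train_ahp(rec.sweeps["stim"][0], n)
        assert amps[1] < -5.0  # the fast AHP of the last AP is present
        assert abs(amps[10] - amps[1]) < 1.0
        assert abs(amps[5] - amps[1]) < 1.0

    def test_detects_injected_slow_hyperpolarization(self, wt_params):
        rec = simulate_current_clamp(wt_params, train_protocol(5), seed=7)
        s = rec.sweeps["stim"][0]
        base = float(s.recorded[: int(90 / s.dt_ms)].mean())
        v = s.recorded.copy()
        i_end = int(np.where(s.command != s.command[0])[0][-1]) + 1
        j0 = i_end + int(300 / s.dt_ms)
        v[j0: j0 + int(100 / s.dt_ms)] = base - 25.0
        doped = Sweep(s.time_ms, v, s.command, mode="current_clamp")
        assert train_ahp(doped, 5) == pytest.approx(-25.0, abs=0.5)

    def test_zero_pulses_is_zero(self, wt_params):
        rec = simulate_current_clamp(wt_params, train_protocol(1), seed=0)
        assert train_ahp(rec.sweeps["stim"][0], 0) == 0.0

    def test_pulse_count_mismatch_raises(self, wt_params):
        rec = simulate_current_clamp(wt_params, train_protocol(5), seed=0)
        with pytest.raises(ValueError, match="mismatch"):
            train_ahp(rec.sweeps["stim"][0], 3)


def test_features_identical_across_zero_variability_cohort():
    from kna_ephys.pipeline import extract_cell_features, _cc_protocols
    from kna_ephys.simulate import make_cohort
    from kna_ephys.datatypes import template_params
    from conftest import quiet
    cells = make_cohort(3, "WT", 10.0, 0.0, seed=5,
                        template=quiet(template_params("WT")),
                        protocols=_cc_protocols())
    feats = [extract_cell_features(c) for c in cells]
    for key in feats[0]:
        vals = [f[key] for f in feats]
        assert all(v == vals[0] or (np.isnan(v) and np.isnan(vals[0]))
                   for v in vals)
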