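"""End-to-end orchestration: simulate cohorts, extract features, compare.

``run_pipeline`` generates WT and KNa-null (dKO) cohorts, measures the full
feature set of every cell (resting potential, input resistance, rheobase,
phase-plane threshold, AP shape, f-I counts, ramp zero crossing), quantifies
the Na-dependent leak current and its Cs block on a reference cell, sweeps
the chord-conductance model, and writes a deterministic report bundle of
CSV/JSON files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import biophys, features, leak
from .datatypes import CellRecord, ProtocolSpec, standard_protocols, ChordModel
from .groupstats import TABLE_ROWS, compare_cohorts, summarize_table
from .simulate import (
    CS_BLOCK_REFERENCE,
    make_cohort,
    resting_potential,
    simulate_voltage_clamp,
)

__all__ = ["RunConfig", "run_pipeline", "extract_cell_features",
           "PipelineError"]

log = logging.getLogger("kna_ephys")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is in ``stage``."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclasses.dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    n_cells: int = 10
    genotypes: tuple = ("WT", "dKO")
    pipette_na_mm: float = 10.0
    variability: float = 0.2
    leak_times_s: tuple = (10.0, 30.0, 60.0, 120.0, 180.0, 300.0)
    threshold_fraction: float = 0.10
    temperature_c: float = 19.0
    out_dir: str = "kna-report"

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["genotypes"] = list(self.genotypes)
        d["leak_times_s"] = list(self.leak_times_s)
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d["genotypes"] = tuple(d["genotypes"])
        d["leak_times_s"] = tuple(d["leak_times_s"])
        return cls(**d)


def _cc_protocols() -> dict:
    protos = standard_protocols()
    return {
        "fi_steps": protos["fi_steps"],
        "rheobase_steps": protos["rheobase_steps"],
        "ramp": protos["ramp"],
        "rin_step": protos["rin_step"],
    }


def extract_cell_features(cell: CellRecord,
                          threshold_fraction: float = 0.10) -> dict:
    """Full per-cell feature dictionary keyed like the summary-table rows."""
    out = {row: np.nan for row in TABLE_ROWS}
    out["ramp zero crossing (mV)"] = np.nan
    out["Cm (pF)"] = cell.capacitance_pf
    if cell.params is not None:
        out["m.p. (mV)"] = resting_potential(cell.params)
    if "rin_step" in cell.sweeps:
        out["R_in (MOhm)"] = features.input_resistance(cell, "rin_step")
    if "rheobase_steps" in cell.sweeps:
        try:
            out["rheobase (pA)"] = features.rheobase(cell, "rheobase_steps")
        except features.UnboundedRheobaseError:
            pass
        # single-AP shape from a fixed-amplitude 20 ms injection: the
        # smallest spiking sweep at or above 100 pA, so threshold estimates
        # are not confounded by stimulus strength; weaker cells fall back to
        # their first suprathreshold sweep
        sweeps = sorted(cell.sweeps["rheobase_steps"], key=features._sweep_level)
        preferred = [s for s in sweeps if features._sweep_level(s) >= 100.0]
        for s in preferred + sweeps:
            if features.detect_aps(s):
                ev = features.ap_shape_features(s, fraction=threshold_fraction)
                out["dV/dt AP threshold (mV)"] = ev.threshold_v_mv
                out["AP peak (mV)"] = ev.peak_v_mv
                out["AP half-width (ms)"] = ev.half_width_ms
                out["AHP (mV)"] = ev.ahp_min_mv
                break
    if "fi_steps" in cell.sweeps:
        for amp, count in features.fi_curve(cell, "fi_steps"):
            key = f"{amp:g} pA AP count"
            if key in out:
                out[key] = count
    if "ramp" in cell.sweeps:
        try:
            out["ramp zero crossing (mV)"] = features.ramp_zero_crossing(
                cell.sweeps["ramp"][0])
        except features.NoCrossingError:
            pass
    return out


def _json_dump(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and write the report bundle; returns the output dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng_seed = int(config.seed)

    # --- stage 1: cohorts and per-cell features -------------------------
    stage = "cohorts"
    try:
        log.info("stage %s: %d cells per genotype, seed %d",
                 stage, config.n_cells, rng_seed)
        cohort_features: dict = {}
        for gi, genotype in enumerate(config.genotypes):
            cells = make_cohort(
                config.n_cells, genotype, config.pipette_na_mm,
                config.variability, seed=rng_seed + gi,
                protocols=_cc_protocols())
            feats = [extract_cell_features(c, config.threshold_fraction)
                     for c in cells]
            cohort_features[genotype] = {
                key: [f[key] for f in feats] for key in feats[0]}
        table = summarize_table(
            {g: cohort_features[g] for g in config.genotypes})
        table.to_csv(out / "summary_table.csv", float_format="%.6g")
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError(stage, str(exc)) from exc

    # --- stage 2: leak time course --------------------------------------
    stage = "leak"
    try:
        log.info("stage %s", stage)
        protos = standard_protocols()
        ref = make_cohort(1, config.genotypes[0], 70.0, 0.0, seed=rng_seed)[0]
        rec = simulate_voltage_clamp(
            ref.params, protos["leak_step"], 70.0,
            times_since_breakin_s=config.leak_times_s, seed=rng_seed)
        meas, (amp, tau_eq, tau_run) = leak.leak_time_course(rec)
        pd.DataFrame({
            "cell": rec.cell_id,
            "time_since_breakin_s": [m.time_since_breakin_s for m in meas],
            "delta_i_pa": [m.delta_i_pa for m in meas],
        }).to_csv(out / "leak_time_course.csv", index=False,
                  float_format="%.6g")
        _json_dump({"amp_pa": amp, "equilibration_tau_s": tau_eq,
                    "rundown_tau_s": tau_run}, out / "leak_fit.json")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # --- stage 3: Cs block ----------------------------------------------
    stage = "csblock"
    try:
        log.info("stage %s", stage)
        iv = protos["iv_steps"]
        ctrl = simulate_voltage_clamp(ref.params, iv, 70.0, (180.0,),
                                      bath="control", seed=rng_seed + 100)
        blocked = simulate_voltage_clamp(ref.params, iv, 70.0, (180.0,),
                                         bath="Cs20mM", seed=rng_seed + 101)
        baseline = simulate_voltage_clamp(ref.params, iv, 0.0, (180.0,),
                                          bath="control", seed=rng_seed + 102)
        # restrict to potentials negative to the Kdr activation range so the
        # Na-dependent component isolates the KNa current
        pts = leak.fractional_inhibition(
            ctrl, blocked, voltages=np.arange(-125.0, -54.0, 10.0),
            baseline=baseline)
        if len({v for v, _, _ in pts}) < 4:
            # no measurable Na-dependent current (e.g. a KNa-null cohort)
            fit = None
            _json_dump({"skipped": "fewer than 4 voltages carry measurable "
                        "Na-dependent current"}, out / "cs_block_fit.json")
        else:
            fit = leak.fit_cs_block(pts, temperature_c=config.temperature_c)
            _json_dump({
                "a": fit.a, "v_half_mv": fit.v_half_mv, "z": fit.z,
                "temperature_c": fit.temperature_c,
                "residual_norm": fit.residual_norm,
                "reference": {"a": CS_BLOCK_REFERENCE.a,
                              "v_half_mv": CS_BLOCK_REFERENCE.v_half_mv,
                              "z": CS_BLOCK_REFERENCE.z},
                "points": [{"v_mv": v, "fraction": f, "clipped": c}
                           for v, f, c in pts],
            }, out / "cs_block_fit.json")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # --- stage 4: chord model -------------------------------------------
    stage = "chord"
    try:
        log.info("stage %s", stage)
        sweep = biophys.gkna_sweep()
        sweep.to_csv(out / "chord_sweep.csv", index=False, float_format="%.6g")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # --- stage 5: self-checks -------------------------------------------
    stage = "report"
    try:
        log.info("stage %s", stage)
        model = ChordModel()
        vm0 = biophys.chord_vm(model)
        vm1 = biophys.chord_vm(model.with_kna(0.16))
        wt, ko = (cohort_features[g] for g in config.genotypes)

        def _mean(d, key):
            v = np.asarray(d[key], dtype=float)
            v = v[np.isfinite(v)]
            return float(v.mean()) if len(v) else float("nan")

        rheo_cmp = compare_cohorts(
            [x for x in wt["rheobase (pA)"] if np.isfinite(x)],
            [x for x in ko["rheobase (pA)"] if np.isfinite(x)],
            *config.genotypes)
        checks = {
            "chord_baseline_vm_mv": vm0,
            "chord_kna_hyperpolarization_mv": vm1 - vm0,
            "cs_block_depolarized_asymptote":
                (1.0 - fit.a) if fit is not None else None,
            "leak_equilibration_tau_s": tau_eq,
            "rheobase_lower_in_kna_null":
                _mean(ko, "rheobase (pA)") < _mean(wt, "rheobase (pA)"),
            "threshold_more_negative_in_kna_null":
                _mean(ko, "dV/dt AP threshold (mV)")
                < _mean(wt, "dV/dt AP threshold (mV)"),
            "fi_counts_higher_in_kna_null": all(
                _mean(ko, f"{a} pA AP count") >= _mean(wt, f"{a} pA AP count")
                for a in (60, 100, 200)),
            "ramp_crossing_more_negative_in_kna_null":
                _mean(ko, "ramp zero crossing (mV)")
                < _mean(wt, "ramp zero crossing (mV)"),
            "rheobase_p_value": rheo_cmp.p_value,
            "rheobase_test": rheo_cmp.test_used,
        }
        config_echo = json.loads(config.to_json())
        config_echo.pop("out_dir")  # location-independent, byte-reproducible
        _json_dump({"config": config_echo, "checks": checks},
                   out / "report.json")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    log.info("pipeline complete: %s", out)
    return out
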