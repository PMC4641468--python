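"""Reading and writing sweep containers.

A cell record on disk is a directory holding one CSV per sweep (columns
``time_ms, command, recorded``) and a ``record.json`` sidecar describing the
cell (genotype, pipette Na, capacitance), its protocols, per-sweep metadata,
and the generating model parameters when known. The format is plain text so
containers diff cleanly and stream sweep by sweep.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterator

import numpy as np

from .datatypes import CellRecord, NeuronModelParams, ProtocolSpec, Sweep

__all__ = ["write_sweeps", "read_sweeps", "iter_sweeps", "SchemaError"]

SIDECAR = "record.json"
_COLUMNS = ("time_ms", "command", "recorded")
_FLOAT_FMT = "%.10g"


class SchemaError(ValueError):
    """A sweep container violates the expected schema."""


def _protocol_to_dict(p: ProtocolSpec) -> dict:
    d = dataclasses.asdict(p)
    d["levels"] = list(p.levels)
    return d


def _protocol_from_dict(d: dict) -> ProtocolSpec:
    d = dict(d)
    d["levels"] = tuple(d["levels"])
    return ProtocolSpec(**d)


def write_sweeps(record: CellRecord, path) -> Path:
    """Write a cell record to ``path`` (a directory); returns the path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    index = []
    for name, sweeps in record.sweeps.items():
        for k, s in enumerate(sweeps):
            fname = f"{name}_{k:04d}.csv"
            data = np.column_stack([s.time_ms, s.command, s.recorded])
            np.savetxt(path / fname, data, delimiter=",",
                       header=",".join(_COLUMNS), comments="", fmt=_FLOAT_FMT)
            index.append({
                "file": fname, "protocol": name, "mode": s.mode,
                "time_since_breakin_s": s.time_since_breakin_s,
                "bath": s.bath, "level": s.level,
            })
    sidecar = {
        "cell_id": record.cell_id,
        "genotype": record.genotype,
        "pipette_na_mm": record.pipette_na_mm,
        "capacitance_pf": record.capacitance_pf,
        "ib4_positive": record.ib4_positive,
        "protocols": {n: _protocol_to_dict(p) for n, p in record.protocols.items()},
        "sweeps": index,
        "params": record.params.to_dict() if record.params else None,
    }
    with open(path / SIDECAR, "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return path


def _load_sidecar(path: Path) -> dict:
    sidecar = path / SIDECAR
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing sidecar {sidecar}: a sweep container requires "
            f"a {SIDECAR} file next to its CSV sweeps")
    with open(sidecar) as fh:
        return json.load(fh)


def _read_sweep_csv(path: Path, entry: dict) -> Sweep:
    fname = path / entry["file"]
    with open(fname) as fh:
        header = fh.readline().strip().split(",")
        if tuple(header) != _COLUMNS:
            raise SchemaError(
                f"{fname}: expected columns {_COLUMNS}, found {tuple(header)}")
        data = np.loadtxt(fh, delimiter=",", ndmin=2)
    if data.shape[1] != 3:
        raise SchemaError(f"{fname}: expected 3 columns, found {data.shape[1]}")
    return Sweep(time_ms=data[:, 0], command=data[:, 1], recorded=data[:, 2],
                 mode=entry["mode"],
                 time_since_breakin_s=entry["time_since_breakin_s"],
                 bath=entry["bath"], level=entry["level"])


def iter_sweeps(path) -> Iterator[tuple]:
    """Stream (protocol_name, Sweep) pairs one at a time from a container."""
    path = Path(path)
    meta = _load_sidecar(path)
    for entry in meta["sweeps"]:
        yield entry["protocol"], _read_sweep_csv(path, entry)


def read_sweeps(path) -> CellRecord:
    """Read a cell record written by :func:`write_sweeps`."""
    path = Path(path)
    meta = _load_sidecar(path)
    record = CellRecord(
        cell_id=meta["cell_id"], genotype=meta["genotype"],
        pipette_na_mm=meta["pipette_na_mm"],
        capacitance_pf=meta["capacitance_pf"],
        ib4_positive=meta["ib4_positive"],
        protocols={n: _protocol_from_dict(d)
                   for n, d in meta["protocols"].items()},
        params=(NeuronModelParams.from_dict(meta["params"])
                if meta.get("params") else None),
    )
    for name, sweep in iter_sweeps(path):
        if name not in record.protocols:
            raise SchemaError(f"sweep references unknown protocol {name!r}")
        record.sweeps.setdefault(name, []).append(sweep)
    return record
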