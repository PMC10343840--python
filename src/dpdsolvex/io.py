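"""Configuration files, trajectory writers, tables, checkpoints, manifests.

All routine outputs are plain text: YAML configs, XYZ and LAMMPS-dump
trajectories, TSV tables and a JSON run manifest.  Checkpoints (positions,
velocities, species, cached forces, step counter) are NumPy ``.npz``
archives and restart a run bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exchange import ExchangeRecord, records_to_rows
from .model import ChainTopology, ScenarioConfig, topology_from_string
from .state import SPECIES_LABELS, SystemState

# -- scenario configuration -------------------------------------------------


def config_to_dict(config: ScenarioConfig) -> dict:
    d = dataclasses.asdict(config)
    d["topology"] = str(config.topology)
    return d


def config_from_dict(d: dict) -> ScenarioConfig:
    d = dict(d)
    topo = d.get("topology", "A2B12")
    if isinstance(topo, str):
        d["topology"] = topology_from_string(topo)
    unknown = set(d) - {f.name for f in dataclasses.fields(ScenarioConfig)}
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    return ScenarioConfig(**d)


def save_config(config: ScenarioConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config),
                                         sort_keys=False))


def load_config(path: str | Path) -> ScenarioConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))


# -- trajectories ------------------------------------------------------------


def write_xyz(state: SystemState, path: str | Path, append: bool = False,
              comment: str | None = None) -> None:
    """One XYZ frame: species label and coordinates per bead."""
    mode = "a" if append else "w"
    labels = np.asarray(SPECIES_LABELS)[state.species]
    with open(path, mode) as fh:
        fh.write(f"{state.n_beads}\n")
        fh.write(comment or f"step={state.step} box={state.box_edge}\n")
        for lab, (x, y, z) in zip(labels, state.positions):
            fh.write(f"{lab} {x:.8f} {y:.8f} {z:.8f}\n")


def read_xyz_frames(path: str | Path) -> list[tuple[dict, np.ndarray, np.ndarray]]:
    """All frames of an XYZ file as (header dict, species codes, positions)."""
    codes = {lab: i for i, lab in enumerate(SPECIES_LABELS)}
    frames = []
    lines = Path(path).read_text().splitlines()
    k = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        n = int(lines[k])
        header = {}
        for token in lines[k + 1].split():
            if "=" in token:
                key, val = token.split("=", 1)
                header[key] = float(val)
        block = lines[k + 2:k + 2 + n]
        species = np.array([codes[row.split()[0]] for row in block],
                           dtype=np.int8)
        pos = np.array([[float(v) for v in row.split()[1:4]] for row in block])
        frames.append((header, species, pos))
        k += 2 + n
    return frames


def write_lammps_dump(state: SystemState, path: str | Path,
                      append: bool = False) -> None:
    """One LAMMPS-dump-style text frame with box bounds."""
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write("ITEM: TIMESTEP\n")
        fh.write(f"{state.step}\n")
        fh.write("ITEM: NUMBER OF ATOMS\n")
        fh.write(f"{state.n_beads}\n")
        fh.write("ITEM: BOX BOUNDS pp pp pp\n")
        for _ in range(3):
            fh.write(f"0.0 {state.box_edge}\n")
        fh.write("ITEM: ATOMS id type x y z\n")
        for i, (sp, (x, y, z)) in enumerate(zip(state.species,
                                                state.positions), start=1):
            fh.write(f"{i} {sp + 1} {x:.8f} {y:.8f} {z:.8f}\n")


# -- tables ------------------------------------------------------------------


def write_exchange_ledger(records: Sequence[ExchangeRecord],
                          path: str | Path) -> None:
    pd.DataFrame(records_to_rows(records)).to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# -- checkpoints -------------------------------------------------------------


def save_checkpoint(state: SystemState, path: str | Path) -> None:
    np.savez_compressed(
        path, positions=state.positions, velocities=state.velocities,
        species=state.species, bonds=state.bonds, chain_of=state.chain_of,
        box_edge=state.box_edge, step=state.step,
        forces=(np.empty((0, 3)) if state.forces is None else state.forces))


def load_checkpoint(path: str | Path) -> SystemState:
    with np.load(path) as data:
        forces = data["forces"]
        return SystemState(
            positions=data["positions"], velocities=data["velocities"],
            species=data["species"], bonds=data["bonds"],
            box_edge=float(data["box_edge"]), chain_of=data["chain_of"],
            step=int(data["step"]),
            forces=None if forces.size == 0 else forces)


# -- run manifest ------------------------------------------------------------


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path: str | Path, config: ScenarioConfig,
                   stages: dict[str, int],
                   outputs: Iterable[str | Path]) -> dict:
    """JSON manifest: config snapshot, seeds, stage step counts, and the
    output inventory with checksums.  Returns the manifest dict."""
    manifest = {
        "package": "dpdsolvex",
        "version": __version__,
        "config": config_to_dict(config),
        "seeds": {"placement": config.placement_seed,
                  "engine": config.engine_seed,
                  "exchange": config.exchange_seed},
        "stages": dict(stages),
        "outputs": {str(p): file_checksum(p) for p in outputs},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
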