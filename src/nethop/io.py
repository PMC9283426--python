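"""Standard-format writers, configuration round-trip and seed management.

Meshes go out as OFF or legacy-ASCII VTK polydata, bead networks as XYZ
plus a JSON adjacency sidecar, curves and tables as CSV with unit-bearing
headers (lengths in a_x, times in tau, energies in k_B T).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cells import BeadSpringNetwork, PolyhedralCell

__all__ = [
    "seed_tree",
    "write_off",
    "write_vtk_polydata",
    "write_xyz",
    "write_network_json",
    "write_profile_csv",
    "write_manifest",
    "load_config",
    "dump_config",
]


def seed_tree(base_seed: int, n: int) -> list[int]:
    """Deterministic child seeds below 2^31 derived from one base seed."""
    ss = np.random.SeedSequence(base_seed)
    return [int(s) for s in ss.generate_state(n) % (2**31 - 1)]


def write_off(cell: PolyhedralCell, path) -> None:
    """Write the cell mesh in OFF polygon format."""
    lines = ["OFF", f"{cell.V} {cell.F} {cell.E}"]
    for v in cell.vertices:
        lines.append(f"{v[0]:.12g} {v[1]:.12g} {v[2]:.12g}")
    for f in cell.faces:
        lines.append(" ".join([str(len(f))] + [str(i) for i in f]))
    Path(path).write_text("\n".join(lines) + "\n")


def write_vtk_polydata(cell: PolyhedralCell, path) -> None:
    """Write the cell mesh as legacy-ASCII VTK polydata."""
    lines = [
        "# vtk DataFile Version 3.0",
        f"{cell.name} network cell (g={cell.g_label}, a_x={cell.a_x})",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {cell.V} double",
    ]
    for v in cell.vertices:
        lines.append(f"{v[0]:.12g} {v[1]:.12g} {v[2]:.12g}")
    size = sum(len(f) + 1 for f in cell.faces)
    lines.append(f"POLYGONS {cell.F} {size}")
    for f in cell.faces:
        lines.append(" ".join([str(len(f))] + [str(i) for i in f]))
    lines.append(f"LINES {cell.E} {3 * cell.E}")
    for i, j in cell.edges:
        lines.append(f"2 {i} {j}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_xyz(network: BeadSpringNetwork, path, comment: str = "") -> None:
    """Bead and cross-link coordinates in XYZ format (units of a_x)."""
    lines = [str(network.n_sites), comment or f"bead-spring network, N={network.N}, b={network.b:.6g} a_x"]
    for k, p in enumerate(network.positions):
        label = "X" if network.is_crosslink[k] else "B"
        lines.append(f"{label} {p[0]:.10g} {p[1]:.10g} {p[2]:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_network_json(network: BeadSpringNetwork, path) -> None:
    """Adjacency sidecar: springs, strand membership, pinned sites."""
    payload = {
        "N": network.N,
        "b_ax": network.b,
        "a_x": network.a_x,
        "springs": [[int(i), int(j)] for i, j in network.springs],
        "crosslinks": [int(i) for i in np.where(network.is_crosslink)[0]],
        "pinned": [int(i) for i in np.where(~network.free)[0]],
        "strands": [
            {"i": int(i), "j": int(j), "beads": [int(k) for k in beads]}
            for i, j, beads in network.strands
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def write_profile_csv(z, dF, path, extra: dict | None = None) -> None:
    """MEP profile as CSV with unit-bearing headers."""
    df = pd.DataFrame({"z_ax": np.asarray(z), "dF_kBT": np.asarray(dF)})
    for k, v in (extra or {}).items():
        df[k] = v
    df.to_csv(path, index=False)


def write_manifest(path, config: dict, seeds: list[int]) -> None:
    import hashlib

    blob = json.dumps(config, sort_keys=True, default=str)
    manifest = {
        "config": config,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seeds": seeds,
    }
    Path(path).write_text(json.dumps(manifest, indent=1, default=str))


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_config(config: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=True))
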