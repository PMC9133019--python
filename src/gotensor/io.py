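"""Readers and writers for the formats the tool touches.

PDB reading goes through Biopython (CA atoms, first model, first chain by
default); XYZ is the plain 4-column text format, multi-frame for
trajectories.  Energy and shape time series are TSV tables; identified
actions are structured JSON.  Every run directory gets a provenance record
(config, seed, version) sufficient to reproduce outputs bit-exactly.
"""

from __future__ import annotations

import json
import sys
import warnings
from pathlib import Path

import numpy as np

__all__ = [
    "read_structure",
    "read_pdb_ca",
    "read_xyz",
    "read_xyz_frames",
    "write_pdb_ca",
    "write_xyz",
    "write_xyz_frames",
    "write_energy_table",
    "write_shape_table",
    "write_actions_json",
    "write_provenance",
    "load_config",
]


class StructureParseError(ValueError):
    pass


def read_structure(path, fmt: str | None = None, chain: str | None = None) -> np.ndarray:
    """Ordered C-alpha coordinates from a PDB or XYZ file.

    ``fmt`` defaults from the file suffix ('.pdb' -> pdb, else xyz).
    """
    path = Path(path)
    if fmt is None:
        fmt = "pdb" if path.suffix.lower() in (".pdb", ".ent") else "xyz"
    if fmt == "pdb":
        return read_pdb_ca(path, chain=chain)
    if fmt == "xyz":
        return read_xyz(path)
    raise ValueError(f"unknown format {fmt!r}")


def read_pdb_ca(path, chain: str | None = None) -> np.ndarray:
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("s", str(path))
    models = list(structure)
    if not models:
        raise StructureParseError(f"{path}: no models")
    model = models[0]
    chains = list(model)
    if chain is not None:
        chains = [c for c in chains if c.id == chain]
        if not chains:
            raise StructureParseError(f"{path}: no chain {chain!r}")
    coords = []
    for residue in chains[0]:
        if "CA" in residue:
            coords.append(residue["CA"].coord)
    if not coords:
        raise StructureParseError(f"{path}: no CA atoms")
    return np.array(coords, dtype=float)


def read_xyz(path) -> np.ndarray:
    """First frame of an XYZ file as an (N, 3) array."""
    frames = read_xyz_frames(path, max_frames=1)
    return frames[0][1]


def read_xyz_frames(path, max_frames: int | None = None):
    """All frames of a (multi-frame) XYZ file as [(comment, coords), ...]."""
    frames = []
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            lineno += 1
            if not header.strip():
                break
            try:
                n = int(header)
            except ValueError as err:
                raise StructureParseError(f"{path}:{lineno}: bad atom count") from err
            comment = fh.readline().rstrip("\n")
            lineno += 1
            coords = np.empty((n, 3))
            for k in range(n):
                line = fh.readline()
                lineno += 1
                parts = line.split()
                if len(parts) < 4:
                    raise StructureParseError(f"{path}:{lineno}: bad XYZ record")
                coords[k] = [float(x) for x in parts[1:4]]
            frames.append((comment, coords))
            if max_frames is not None and len(frames) >= max_frames:
                break
    if not frames:
        raise StructureParseError(f"{path}: empty XYZ file")
    return frames


def write_xyz(path, coords: np.ndarray, comment: str = "") -> None:
    write_xyz_frames(path, [(comment, np.asarray(coords, dtype=float))])


def write_xyz_frames(path, frames) -> None:
    with open(path, "w") as fh:
        for comment, coords in frames:
            fh.write(f"{len(coords)}\n{comment}\n")
            for x, y, z in coords:
                fh.write(f"CA {x:.6f} {y:.6f} {z:.6f}\n")


def write_pdb_ca(path, coords: np.ndarray, chain: str = "A") -> None:
    """Minimal CA-only PDB writer (one model, poly-alanine placeholder)."""
    with open(path, "w") as fh:
        for k, (x, y, z) in enumerate(np.asarray(coords, dtype=float), start=1):
            fh.write(
                f"ATOM  {k:5d}  CA  ALA {chain}{k:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f" C  \n"
            )
        fh.write("END\n")


def write_energy_table(path, traj, record_every: int, dt: float) -> None:
    """TSV: step, time, bond, angle, dihedral, native, nonnative, pore, total."""
    import pandas as pd

    cols = ["bond", "angle", "dihedral", "native", "nonnative", "pore", "total"]
    rows = []
    for k, terms in enumerate(traj.energies):
        step = k * record_every
        rows.append([step, traj.frames[k].time] + [terms.get(c, 0.0) for c in cols])
    df = pd.DataFrame(rows, columns=["step", "time"] + cols)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_shape_table(path, times, nu_series, shape_states) -> None:
    """TSV: time, nu components (row-major), U eigenvalues, semi-axes."""
    import pandas as pd

    rows = []
    for t, nu, st in zip(times, nu_series, shape_states):
        lam = np.sort(np.linalg.eigvalsh(st.stretch))[::-1]
        rows.append([t] + list(np.asarray(nu).ravel()) + list(lam) + list(st.semi_axes))
    cols = (["time"] + [f"nu_{i}{j}" for i in range(1, 4) for j in range(1, 4)]
            + [f"lambda_{i}" for i in range(1, 4)] + [f"axis_{i}" for i in range(1, 4)])
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False,
                                            float_format="%.10g")


def _jsonify(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, dict):
        return {k: _jsonify(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonify(v) for v in x]
    return x


def write_actions_json(path, record: dict) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonify(record), fh, indent=1)
        fh.write("\n")


def write_provenance(path, config: dict, seed: int) -> None:
    from . import __version__

    record = {"config": _jsonify(config), "seed": seed,
              "tool": "gotensor", "version": __version__,
              "python": sys.version.split()[0]}
    with open(path, "w") as fh:
        json.dump(record, fh, indent=1)
        fh.write("\n")


def load_config(path) -> dict:
    """TOML run configuration; keys mirror the potential's symbols."""
    import tomllib

    with open(path, "rb") as fh:
        return tomllib.load(fh)
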