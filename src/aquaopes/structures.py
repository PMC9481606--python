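"""Minimal structure/trajectory I/O: XYZ trajectories and a PDB subset.

Writers emit plain-text XYZ and minimal PDB (ATOM/HETATM records only);
reading goes through MDAnalysis so that standard selection syntax
("name CA", "resname HOH") is available for anchor/water selection.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "write_xyz", "read_traj", "write_pdb", "read_structure",
    "write_scene", "load_scene",
]


def write_xyz(path, frames, names, comment: str = "") -> None:
    """Write a multi-frame XYZ trajectory (frames: (n_frames, n_atoms, 3))."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    n_atoms = frames.shape[1]
    if len(names) != n_atoms:
        raise ValueError("one atom name per column required")
    with open(path, "w") as fh:
        for f, frame in enumerate(frames):
            fh.write(f"{n_atoms}\n")
            fh.write(f"{comment} frame {f}\n")
            for name, (x, y, z) in zip(names, frame):
                fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")


def read_traj(path, expected_atoms: int | None = None) -> np.ndarray:
    """Read an XYZ (or multi-model PDB) trajectory into (n_frames, n_atoms, 3)."""
    import MDAnalysis as mda
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        frames = np.array([u.atoms.positions.copy() for _ in u.trajectory],
                          dtype=float)
    if expected_atoms is not None and frames.shape[1] != expected_atoms:
        raise ValueError(
            f"{path}: trajectory has {frames.shape[1]} atoms, "
            f"expected {expected_atoms}")
    return frames


def write_pdb(path, positions, names, resnames, resids,
              chain: str = "A", hetatm=None) -> None:
    """Write a minimal PDB: fixed-width ATOM/HETATM records, no CONECT."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    hetatm = [False] * n if hetatm is None else list(hetatm)
    if not (len(names) == len(resnames) == len(resids) == n):
        raise ValueError("names/resnames/resids must match positions")
    with open(path, "w") as fh:
        for i in range(n):
            rec = "HETATM" if hetatm[i] else "ATOM  "
            x, y, z = positions[i]
            elem = names[i].strip()[0]
            fh.write(f"{rec}{i + 1:>5} {names[i]:<4}{resnames[i]:>4} "
                     f"{chain}{resids[i]:>4}    "
                     f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                     f"          {elem:>2}\n")
        fh.write("END\n")


class AtomTable:
    """Atom metadata + coordinates with MDAnalysis-backed selection."""

    def __init__(self, universe):
        self.universe = universe

    @property
    def n_atoms(self) -> int:
        return len(self.universe.atoms)

    @property
    def names(self):
        return self.universe.atoms.names

    @property
    def positions(self) -> np.ndarray:
        return self.universe.atoms.positions.astype(float)

    def select(self, selection: str) -> np.ndarray:
        """Indices of atoms matching an MDAnalysis selection string."""
        return self.universe.select_atoms(selection).ix

    def select_positions(self, selection: str) -> np.ndarray:
        return self.universe.select_atoms(selection).positions.astype(float)

    def single_atom_position(self, selection: str) -> np.ndarray:
        sel = self.universe.select_atoms(selection)
        if len(sel) != 1:
            raise ValueError(
                f"selector {selection!r} resolves to {len(sel)} atoms, need 1")
        return sel.positions[0].astype(float)


def read_structure(path) -> AtomTable:
    """Read a PDB into an AtomTable (malformed records raise with context)."""
    import MDAnalysis as mda
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse structure: {exc}") from exc
    return AtomTable(u)


# --------------------------------------------------------------------------
# scene convenience: write/read a synthetic water scene as PDB + XYZ
# --------------------------------------------------------------------------

def write_scene(prefix, water_traj, anchor_points):
    """Write topology ``<prefix>.pdb`` + trajectory ``<prefix>.xyz``.

    Anchors appear first as CA records (resname ALA), then water oxygens
    (resname HOH, name OW).  Anchors are static in every XYZ frame.
    """
    n_anchor = len(anchor_points)
    n_w = water_traj.shape[1]
    names = ["CA"] * n_anchor + ["OW"] * n_w
    resnames = ["ALA"] * n_anchor + ["HOH"] * n_w
    resids = list(range(1, n_anchor + 1)) + list(range(101, 101 + n_w))
    first = np.vstack([anchor_points, water_traj[0]])
    write_pdb(f"{prefix}.pdb", first, names, resnames, resids,
              hetatm=[False] * n_anchor + [True] * n_w)
    frames = np.concatenate(
        [np.broadcast_to(anchor_points, (len(water_traj), n_anchor, 3)),
         water_traj], axis=1)
    elems = ["C"] * n_anchor + ["O"] * n_w
    write_xyz(f"{prefix}.xyz", frames, elems, comment="synthetic water scene")


def load_scene(prefix):
    """Read back (water_traj, anchor_points) written by :func:`write_scene`."""
    table = read_structure(f"{prefix}.pdb")
    anchor_idx = table.select("name CA")
    water_idx = table.select("name OW")
    frames = read_traj(f"{prefix}.xyz", expected_atoms=table.n_atoms)
    return frames[:, water_idx], frames[0, anchor_idx]
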