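"""Trajectory container plus PDB and multi-frame XYZ readers/writers.

A :class:`Trajectory` is frames × atoms × 3 Cartesian coordinates in Å with
a per-atom metadata table (chain, residue id/name, atom name, element,
heavy-atom flag, van der Waals radius).  Atom selections use the compact
``chain[:resid[,resid…]]`` syntax, e.g. ``"P"`` (whole chain) or ``"P:3"``
(residue 3 of chain P), with residue ids 1-based as in PDB numbering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "VDW_RADII",
    "read_pdb",
    "write_pdb",
    "read_xyz",
    "write_xyz",
]

# Bondi-style van der Waals radii (Å) by element symbol.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
}
DEFAULT_VDW_RADIUS = 1.70

ATOM_COLUMNS = ["name", "resid", "resname", "chain", "element"]


def _element_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW_RADIUS)


def make_atom_table(
    names: Sequence[str],
    resids: Sequence[int],
    resnames: Sequence[str],
    chains: Sequence[str],
    elements: Sequence[str],
) -> pd.DataFrame:
    """Assemble the per-atom metadata table, deriving radius and heavy flag."""
    df = pd.DataFrame({
        "name": list(names),
        "resid": np.asarray(resids, dtype=int),
        "resname": list(resnames),
        "chain": list(chains),
        "element": [e.upper() for e in elements],
    })
    df["is_heavy"] = df["element"] != "H"
    df["vdw_radius"] = [_element_radius(e) for e in df["element"]]
    return df


@dataclass
class Trajectory:
    """Multi-frame coordinate set with per-atom metadata.

    Attributes
    ----------
    coords : ndarray, shape (n_frames, n_atoms, 3)
        Cartesian coordinates in Å.
    atoms : DataFrame
        One row per atom: name, resid, resname, chain, element, is_heavy,
        vdw_radius.
    """

    coords: np.ndarray
    atoms: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim == 2:
            self.coords = self.coords[None, :, :]
        if self.coords.ndim != 3 or self.coords.shape[-1] != 3:
            raise ValueError(
                f"coords must have shape (frames, atoms, 3), got "
                f"{self.coords.shape}"
            )
        if self.coords.shape[1] != len(self.atoms):
            raise ValueError(
                f"{self.coords.shape[1]} coordinates per frame but "
                f"{len(self.atoms)} atoms in the metadata table"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinate in trajectory")
        self.atoms = self.atoms.reset_index(drop=True)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> "Trajectory":
        """Single-frame view as a new Trajectory."""
        return Trajectory(self.coords[i][None, :, :].copy(), self.atoms)

    def select(self, selector: str, heavy_only: bool = False) -> np.ndarray:
        """Atom indices matching a ``chain[:resid[,resid…]]`` selector."""
        sel = selector.strip()
        if not sel:
            raise ValueError("empty selector")
        parts = sel.split(":")
        if len(parts) > 2:
            raise ValueError(f"bad selector {selector!r}; use chain[:resid]")
        mask = (self.atoms["chain"] == parts[0]).to_numpy()
        if len(parts) == 2:
            try:
                resids = {int(r) for r in parts[1].split(",")}
            except ValueError as exc:
                raise ValueError(
                    f"bad residue id in selector {selector!r}"
                ) from exc
            mask &= self.atoms["resid"].isin(resids).to_numpy()
        if heavy_only:
            mask &= self.atoms["is_heavy"].to_numpy()
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            raise ValueError(f"selector {selector!r} matched no atoms")
        return idx

    def subset(self, indices: np.ndarray) -> "Trajectory":
        return Trajectory(
            self.coords[:, indices, :].copy(),
            self.atoms.iloc[indices].reset_index(drop=True),
        )


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def read_pdb(path: str | Path) -> Trajectory:
    """Parse ATOM/HETATM records of a PDB file into a single-frame Trajectory.

    Fixed-column parsing; 1-based residue numbering is preserved; where
    alternate locations exist only the first conformer of each atom is
    kept.  Malformed records raise ``ValueError`` naming the line number.
    """
    path = Path(path)
    names, resids, resnames, chains, elements = [], [], [], [], []
    xyz: list[list[float]] = []
    seen_alt: set[tuple] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            try:
                name = line[12:16].strip()
                altloc = line[16].strip()
                resname = line[17:20].strip()
                chain = line[21].strip() or "A"
                resid = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                element = line[76:78].strip() if len(line) >= 77 else ""
            except (ValueError, IndexError) as exc:
                raise ValueError(
                    f"{path}:{lineno}: unreadable {rec} record"
                ) from exc
            if altloc:
                key = (chain, resid, name)
                if key in seen_alt:
                    continue
                seen_alt.add(key)
            if not element:
                # fall back on the first alphabetic character of the name
                stripped = name.lstrip("0123456789")
                element = stripped[:1] or "C"
            names.append(name)
            resids.append(resid)
            resnames.append(resname)
            chains.append(chain)
            elements.append(element)
            xyz.append([x, y, z])
    if not xyz:
        raise ValueError(f"{path}: no ATOM/HETATM records found")
    atoms = make_atom_table(names, resids, resnames, chains, elements)
    return Trajectory(np.array(xyz)[None, :, :], atoms)


def write_pdb(traj: Trajectory, path: str | Path, frame: int = 0) -> None:
    """Write one frame as PDB ATOM records (coordinates to 3 decimals)."""
    path = Path(path)
    coords = traj.coords[frame]
    with path.open("w") as fh:
        for i, (row, (x, y, z)) in enumerate(
            zip(traj.atoms.itertuples(index=False), coords), start=1
        ):
            name = row.name if len(row.name) >= 4 else f" {row.name:<3s}"
            fh.write(
                f"ATOM  {i:5d} {name:<4.4s} {row.resname:<3.3s} "
                f"{row.chain:1.1s}{row.resid:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
                f"{row.element:>2.2s}\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Multi-frame XYZ
# ---------------------------------------------------------------------------

def write_xyz(traj: Trajectory, path: str | Path) -> None:
    """Write all frames in the multi-frame XYZ dialect (element x y z)."""
    path = Path(path)
    elements = traj.atoms["element"].tolist()
    with path.open("w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n")
            fh.write(f"frame {f}\n")
            for el, (x, y, z) in zip(elements, traj.coords[f]):
                fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path: str | Path, topology: Trajectory | pd.DataFrame) -> Trajectory:
    """Read a multi-frame XYZ file, attaching metadata from a topology.

    The topology (a parsed PDB or its atom table) supplies chain/residue
    labels; the XYZ file supplies coordinates for every frame.  Atom counts
    must agree.
    """
    atoms = topology.atoms if isinstance(topology, Trajectory) else topology
    path = Path(path)
    frames: list[np.ndarray] = []
    with path.open() as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"{path}:{i + 1}: expected atom count") from exc
        block = lines[i + 2: i + 2 + n]
        if len(block) < n:
            raise ValueError(f"{path}:{i + 1}: truncated frame")
        coords = np.array(
            [[float(v) for v in ln.split()[1:4]] for ln in block]
        )
        frames.append(coords)
        i += 2 + n
    if not frames:
        raise ValueError(f"{path}: no frames found")
    arr = np.stack(frames)
    if arr.shape[1] != len(atoms):
        raise ValueError(
            f"{path}: {arr.shape[1]} atoms per frame but topology has "
            f"{len(atoms)}"
        )
    return Trajectory(arr, atoms)
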