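"""Trajectory-derived binding statistics for peptide–receptor complexes.

Implements the per-residue measures used to characterise how a peptide
ligand engages its receptor over simulation trajectories:

* **contact probability** — fraction of analysed (tail-window, pooled over
  replicas) frames in which any heavy-atom pair of two selections comes
  within a distance cutoff;
* **key-residue filter** — residues whose contact probability exceeds a
  threshold (default 50%);
* **SASA** (Shrake–Rupley) and the **contact-area ratio** — the fraction
  of a peptide residue's isolated solvent-accessible surface buried upon
  complexation, ∈ [0, 1];
* **pair-distance series** and geometric **hydrogen-bond occupancy**;
* **Kabsch RMSD** after optimal rigid-body superposition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .trajectory import Trajectory

__all__ = [
    "ContactSpec",
    "ResidueContactProfile",
    "contact_probability",
    "key_residue_filter",
    "sasa",
    "contact_area_ratio",
    "pair_distance_series",
    "hydrogen_bond_occupancy",
    "kabsch_rmsd",
    "rmsd_series",
    "tail_mean",
]


@dataclass(frozen=True)
class ContactSpec:
    """Contact definition: heavy-atom distance cutoff and analysis window.

    ``tail_fraction`` selects the final fraction of frames of every
    trajectory (half-open window), the synthetic stand-in for analysing
    only the converged tail of a production run.
    """

    cutoff: float = 4.5  # Å
    tail_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if not 0 < self.tail_fraction <= 1:
            raise ValueError("tail_fraction must be in (0, 1]")


@dataclass(frozen=True)
class ResidueContactProfile:
    """Per-residue contact probability and/or contact-area ratio."""

    contact_probability: dict[int, float] = field(default_factory=dict)
    contact_area_ratio: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for d in (self.contact_probability, self.contact_area_ratio):
            for r, v in d.items():
                if not math.isnan(v) and not 0.0 <= v <= 1.0:
                    raise ValueError(
                        f"profile value for residue {r} outside [0, 1]: {v}"
                    )


def _tail_slice(n_frames: int, tail_fraction: float) -> slice:
    n_tail = int(round(tail_fraction * n_frames))
    if n_tail < 1:
        raise ValueError(
            f"tail window of zero frames ({n_frames} frames × "
            f"{tail_fraction} tail fraction)"
        )
    return slice(n_frames - n_tail, n_frames)


def contact_probability(
    trajectories: Sequence[Trajectory] | Trajectory,
    residue: str,
    partner: str,
    spec: ContactSpec = ContactSpec(),
) -> float:
    """Pooled contact probability of two selections over replica tails.

    Counts, over the tail windows of all replicas pooled, the frames in
    which the minimum heavy-atom distance between ``residue`` and
    ``partner`` is below the cutoff, divided by the total pooled tail
    frames.
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    if not trajectories:
        raise ValueError("no trajectories supplied")
    hits = total = 0
    for traj in trajectories:
        ia = traj.select(residue, heavy_only=True)
        ib = traj.select(partner, heavy_only=True)
        window = _tail_slice(traj.n_frames, spec.tail_fraction)
        for frame in traj.coords[window]:
            dmin = cdist(frame[ia], frame[ib]).min()
            hits += dmin < spec.cutoff
            total += 1
    return hits / total


def key_residue_filter(
    profile: ResidueContactProfile | Mapping[int, float],
    threshold: float = 0.5,
) -> list[int]:
    """Residues with contact probability strictly above the threshold.

    The default 0.5 reproduces the "contact ratio larger than 50%"
    criterion for calling a receptor residue a key binding residue.
    Returned sorted by residue id.
    """
    probs = (
        profile.contact_probability
        if isinstance(profile, ResidueContactProfile)
        else profile
    )
    return sorted(r for r, p in probs.items() if p > threshold)


# ---------------------------------------------------------------------------
# SASA (Shrake–Rupley)
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area, Shrake–Rupley.

    Each atom is dressed with ``n_points`` test points on a sphere of
    radius r_i + probe; a point is buried if it falls inside any other
    atom's probe-expanded sphere.  Accessible area is the unburied
    fraction of 4π(r_i + probe)².  Deterministic (fixed point set).
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if coords.ndim != 2 or coords.shape[0] == 0:
        raise ValueError("sasa requires at least one atom")
    if np.any(radii <= 0):
        raise ValueError("all radii must be positive")
    n = coords.shape[0]
    sphere = _sphere_points(n_points)
    expanded = radii + probe_radius
    out = np.empty(n)
    # neighbour prefilter: only atoms whose expanded spheres can overlap
    pair_d = cdist(coords, coords)
    for i in range(n):
        pts = coords[i] + expanded[i] * sphere
        cutoff = expanded[i] + expanded
        nbr = np.nonzero((pair_d[i] < cutoff) & (np.arange(n) != i))[0]
        if nbr.size:
            buried = (
                cdist(pts, coords[nbr]) < expanded[nbr][None, :]
            ).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        out[i] = frac * 4.0 * math.pi * expanded[i] ** 2
    return out


def residue_sasa(
    traj: Trajectory,
    frame: int = 0,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> dict[tuple[str, int], float]:
    """Per-residue SASA (sum over atoms) keyed by (chain, resid)."""
    areas = sasa(
        traj.coords[frame], traj.atoms["vdw_radius"].to_numpy(),
        probe_radius, n_points,
    )
    df = traj.atoms.assign(area=areas)
    grouped = df.groupby(["chain", "resid"], sort=False)["area"].sum()
    return {k: float(v) for k, v in grouped.items()}


def contact_area_ratio(
    traj: Trajectory,
    peptide_chain: str,
    receptor_chain: str,
    frame: int = 0,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> ResidueContactProfile:
    """Buried fraction of each peptide residue's surface upon complexation.

    For every residue of the peptide chain:
    (SASA in the isolated peptide − SASA in the complex) / isolated SASA,
    clamped to [0, 1].  A residue whose isolated SASA is zero gets NaN
    (undefined) rather than a fabricated ratio.  Residues ~fully enclosed
    by the receptor approach 1.0; chains far apart give 0.0 everywhere.
    """
    pep_idx = traj.select(peptide_chain)
    traj.select(receptor_chain)  # validates the receptor chain exists
    isolated = traj.subset(pep_idx)

    iso = residue_sasa(isolated, frame, probe_radius, n_points)
    in_complex = residue_sasa(traj, frame, probe_radius, n_points)

    ratios: dict[int, float] = {}
    for (chain, resid), iso_area in iso.items():
        if chain != peptide_chain.split(":")[0]:
            continue
        if iso_area <= 0:
            ratios[resid] = math.nan
            continue
        buried = iso_area - in_complex[(chain, resid)]
        ratios[resid] = min(1.0, max(0.0, buried / iso_area))
    return ResidueContactProfile(contact_area_ratio=ratios)


# ---------------------------------------------------------------------------
# Distances and hydrogen bonds
# ---------------------------------------------------------------------------

def pair_distance_series(
    traj: Trajectory, group_a: str, group_b: str
) -> np.ndarray:
    """Per-frame minimum heavy-atom distance between two selections (Å).

    Atom indices common to both selections are excluded as self-pairs.
    """
    ia = traj.select(group_a, heavy_only=True)
    ib = traj.select(group_b, heavy_only=True)
    shared = np.intersect1d(ia, ib)
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        d = cdist(traj.coords[f][ia], traj.coords[f][ib])
        if shared.size:
            for s in shared:
                d[np.nonzero(ia == s)[0], np.nonzero(ib == s)[0]] = np.inf
        out[f] = d.min()
    if not np.all(np.isfinite(out)):
        raise ValueError("selections contain only self-pairs")
    return out


def hydrogen_bond_occupancy(
    traj: Trajectory,
    donors: str,
    acceptors: str,
    d_cut: float = 3.5,
    angle_cut: float = 30.0,
) -> pd.DataFrame:
    """Geometric hydrogen-bond occupancy for every donor–acceptor pair.

    A bond is counted in a frame when the donor–acceptor heavy-atom
    distance is below ``d_cut`` and the D–H…A arrangement deviates from
    linearity by less than ``angle_cut`` degrees for any hydrogen attached
    to the donor (same residue, within 1.3 Å in the first frame).  Donors
    without an attached hydrogen are an error, listing the offenders.
    """
    don_idx = traj.select(donors, heavy_only=True)
    acc_idx = traj.select(acceptors, heavy_only=True)
    atoms = traj.atoms
    h_idx = np.nonzero((atoms["element"] == "H").to_numpy())[0]

    attached: dict[int, list[int]] = {}
    missing = []
    for d in don_idx:
        hs = []
        for h in h_idx:
            same_res = (
                atoms.at[int(h), "chain"] == atoms.at[int(d), "chain"]
                and atoms.at[int(h), "resid"] == atoms.at[int(d), "resid"]
            )
            if same_res and np.linalg.norm(
                traj.coords[0, h] - traj.coords[0, d]
            ) < 1.3:
                hs.append(int(h))
        if not hs:
            row = atoms.iloc[int(d)]
            missing.append(f"{row['chain']}:{row['resid']}:{row['name']}")
        attached[int(d)] = hs
    if missing:
        raise ValueError(
            "donor atoms lack an attached hydrogen: " + ", ".join(missing)
        )

    def label(i: int) -> str:
        row = atoms.iloc[int(i)]
        return f"{row['chain']}:{row['resid']}:{row['name']}"

    records = []
    for d in don_idx:
        for a in acc_idx:
            if int(a) == int(d):
                continue
            bonded = 0
            for f in range(traj.n_frames):
                da = np.linalg.norm(traj.coords[f, a] - traj.coords[f, d])
                if da >= d_cut:
                    continue
                for h in attached[int(d)]:
                    hd = traj.coords[f, d] - traj.coords[f, h]
                    ha = traj.coords[f, a] - traj.coords[f, h]
                    cosang = np.dot(hd, ha) / (
                        np.linalg.norm(hd) * np.linalg.norm(ha)
                    )
                    angle = math.degrees(math.acos(np.clip(cosang, -1, 1)))
                    # D-H…A deviation from linearity = 180° − ∠(D,H,A)
                    if 180.0 - angle < angle_cut:
                        bonded += 1
                        break
            records.append({
                "donor": label(d),
                "acceptor": label(a),
                "occupancy": bonded / traj.n_frames,
            })
    return pd.DataFrame(records, columns=["donor", "acceptor", "occupancy"])


# ---------------------------------------------------------------------------
# Kabsch RMSD
# ---------------------------------------------------------------------------

def kabsch_rmsd(reference: np.ndarray, mobile: np.ndarray) -> float:
    """RMSD after optimal rigid superposition (rotation + translation).

    Kabsch algorithm via SVD with determinant correction, so reflections
    are never applied.  Requires at least three non-collinear points.
    """
    ref = np.asarray(reference, dtype=float)
    mob = np.asarray(mobile, dtype=float)
    if ref.shape != mob.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError(
            f"coordinate sets must share shape (n, 3); got {ref.shape} "
            f"and {mob.shape}"
        )
    n = ref.shape[0]
    if n < 3:
        raise ValueError("superposition requires at least 3 atoms")
    rc = ref - ref.mean(axis=0)
    mc = mob - mob.mean(axis=0)
    if np.linalg.matrix_rank(rc, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) reference geometry")
    h = mc.T @ rc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    aligned = mc @ rot.T
    return float(np.sqrt(((aligned - rc) ** 2).sum() / n))


def rmsd_series(
    traj: Trajectory,
    reference: np.ndarray | None = None,
    selection: str | None = None,
) -> np.ndarray:
    """Per-frame Kabsch RMSD against a reference frame.

    ``reference`` defaults to the first frame; ``selection`` restricts the
    atoms used for both fitting and measurement.
    """
    idx = (
        traj.select(selection)
        if selection is not None
        else np.arange(traj.n_atoms)
    )
    ref = (
        np.asarray(reference, dtype=float)[idx]
        if reference is not None and np.asarray(reference).shape[0] == traj.n_atoms
        else (np.asarray(reference, dtype=float) if reference is not None
              else traj.coords[0][idx])
    )
    return np.array([
        kabsch_rmsd(ref, traj.coords[f][idx]) for f in range(traj.n_frames)
    ])


def tail_mean(series: Sequence[float], tail_fraction: float = 0.1) -> float:
    """Mean of the final ``tail_fraction`` of a series (half-open window)."""
    arr = np.asarray(series, dtype=float)
    window = _tail_slice(arr.size, tail_fraction)
    return float(arr[window].mean())
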