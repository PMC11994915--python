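"""Analytically tractable toy alchemical systems and synthetic trajectories.

The windowed free-energy estimator needs Boltzmann-distributed
configurations of the mixed potential V(λ) = (1−λ)V1 + λV2 at every λ.
Instead of atomistic molecular dynamics, this module samples small
closed-form systems (isotropic harmonic wells, a single soft-core
Lennard-Jones particle among fixed neighbours) with Metropolis Monte
Carlo.  The harmonic pair has an exact free-energy difference,
ΔG = (d/2)·kBT·ln(k2/k1), and any 1-D/2-D pair can be integrated directly
(−kBT·ln(Z2/Z1) by quadrature), giving two independent ground truths for
the estimator.

It also fabricates two-chain bead trajectories with a prescribed
per-residue contact on/off schedule and Gaussian positional noise, so the
trajectory statistics (contact probability, contact-area ratio, distance
series, RMSD) can be checked against constructed truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .alchemy import (
    LambdaSchedule,
    State,
    WindowSamples,
    softcore_pair_energy,
)
from .thermo import ThermoState
from .trajectory import Trajectory, make_atom_table

__all__ = [
    "HarmonicWell",
    "LJParticle",
    "MixedPotential",
    "MCConfig",
    "MCResult",
    "metropolis_sample",
    "generate_window_samples",
    "analytic_harmonic_dg",
    "quadrature_dg",
    "ChainSpec",
    "SyntheticTrajectorySpec",
    "generate_toy_trajectory",
]


# ---------------------------------------------------------------------------
# Toy potentials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HarmonicWell:
    """Isotropic harmonic well V(x) = ½·k·|x − center|².

    By package convention the harmonic energy is booked entirely as van der
    Waals, so harmonic-pair transformations provide an exactly-zero
    electrostatic leg for decomposition tests.
    """

    k: float  # kcal/mol/Å²
    center: tuple[float, ...] = (0.0,)
    dim: int = 1

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError(f"spring constant must be positive, got {self.k}")
        c = tuple(float(v) for v in self.center)
        if len(c) != self.dim:
            c = tuple(c[i] if i < len(c) else 0.0 for i in range(self.dim))
        object.__setattr__(self, "center", c)

    def energy_components(self, x: np.ndarray) -> tuple[float, float]:
        """(elec, vdw) energies at position x."""
        d = np.asarray(x, dtype=float) - np.asarray(self.center)
        return 0.0, 0.5 * self.k * float(d @ d)

    def energy(self, x: np.ndarray) -> float:
        e, v = self.energy_components(x)
        return e + v

    def initial_position(self) -> np.ndarray:
        return np.array(self.center, dtype=float)


@dataclass(frozen=True)
class LJParticle:
    """One mobile soft-core LJ (+ optional Coulomb) particle in a box.

    The particle interacts with fixed neighbour sites through the
    Beutler-style soft-core pair potential at coupling ``softcore_lambda``
    (0 = fully coupled plain LJ, 1 = fully decoupled) and is confined to a
    cubic box of side ``box_length`` by hard walls.
    """

    sigma: float  # Å
    epsilon: float  # kcal/mol
    neighbors: tuple[tuple[float, ...], ...]
    box_length: float  # Å
    dim: int = 1
    charge_product: float = 0.0  # e²
    softcore_lambda: float = 0.0
    alpha: float = 0.5

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be nonnegative")
        if self.box_length <= 2 * self.sigma:
            raise ValueError("box length must exceed 2*sigma")
        object.__setattr__(
            self,
            "neighbors",
            tuple(tuple(float(v) for v in n) for n in self.neighbors),
        )

    def in_box(self, x: np.ndarray) -> bool:
        return bool(np.all(np.abs(x) <= self.box_length / 2))

    def energy_components(self, x: np.ndarray) -> tuple[float, float]:
        x = np.asarray(x, dtype=float)
        if not self.in_box(x):
            return 0.0, math.inf
        elec = vdw = 0.0
        for n in self.neighbors:
            r = float(np.linalg.norm(x - np.asarray(n)))
            comp = softcore_pair_energy(
                max(r, 1e-12), self.softcore_lambda, self.sigma, self.epsilon,
                alpha=self.alpha, charge_product=self.charge_product,
            )
            elec += comp.elec
            vdw += comp.vdw
        return elec, vdw

    def energy(self, x: np.ndarray) -> float:
        e, v = self.energy_components(x)
        return e + v

    def initial_position(self) -> np.ndarray:
        """Deterministic low-energy start: the in-box point farthest from
        neighbours along a coarse grid scan."""
        grid = np.linspace(
            -self.box_length / 2 * 0.9, self.box_length / 2 * 0.9, 11
        )
        pts = np.stack(
            np.meshgrid(*([grid] * self.dim)), axis=-1
        ).reshape(-1, self.dim)
        energies = np.array([self.energy(p) for p in pts])
        return pts[int(np.argmin(energies))].astype(float)


@dataclass(frozen=True)
class MixedPotential:
    """Alchemically mixed potential V(λ) = (1−λ)·V1 + λ·V2."""

    v1: object
    v2: object
    lam: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError(f"lambda must be in [0, 1], got {self.lam}")

    def energy_components(self, x: np.ndarray) -> tuple[float, float]:
        e1, w1 = self.v1.energy_components(x)
        e2, w2 = self.v2.energy_components(x)

        def mix(a: float, b: float) -> float:
            # avoid 0·inf at the end points when one state is hard-wall inf
            tot = 0.0
            if self.lam < 1.0:
                tot += (1.0 - self.lam) * a
            if self.lam > 0.0:
                tot += self.lam * b
            return tot

        return mix(e1, e2), mix(w1, w2)

    def energy(self, x: np.ndarray) -> float:
        e, v = self.energy_components(x)
        return e + v

    def initial_position(self) -> np.ndarray:
        return self.v1.initial_position()


# ---------------------------------------------------------------------------
# Metropolis Monte Carlo
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MCConfig:
    """Monte Carlo sampling settings for one window chain."""

    n_steps: int = 1000
    equilibration_steps: int = 200
    step_size: float = 0.5  # Å
    seed: int = 0
    n_replicas: int = 6

    def __post_init__(self) -> None:
        if self.equilibration_steps < 0:
            raise ValueError("equilibration_steps must be >= 0")
        if self.n_steps <= 0:
            raise ValueError("n_steps must be positive")
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if self.n_replicas < 1:
            raise ValueError("n_replicas must be >= 1")


@dataclass
class MCResult:
    """Production samples of one Metropolis chain."""

    positions: np.ndarray  # (n_steps, dim)
    energies: np.ndarray  # (n_steps,)
    acceptance_fraction: float
    step_size: float  # frozen production step size


#: Target acceptance fraction for step-size auto-tuning.
_TARGET_ACCEPTANCE = 0.4


def metropolis_sample(
    potential,
    config: MCConfig,
    thermo: ThermoState,
    rng: np.random.Generator | None = None,
) -> MCResult:
    """Metropolis chain under ``potential`` at inverse temperature β.

    Gaussian displacement proposals; acceptance min(1, exp(−βΔE)).  During
    equilibration the step size is adapted toward ~40% acceptance, then
    frozen for production so detailed balance holds for every recorded
    sample.  Deterministic given the config seed (or an explicit
    generator).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    x = np.atleast_1d(np.asarray(potential.initial_position(), dtype=float))
    dim = x.size
    e = potential.energy(x)
    if not math.isfinite(e):
        raise ValueError("potential energy non-finite at the starting point")
    step = config.step_size
    beta = thermo.beta

    # equilibration with step-size adaptation
    acc_block = 0
    for i in range(config.equilibration_steps):
        prop = x + rng.normal(scale=step, size=dim)
        e_prop = potential.energy(prop)
        if e_prop != math.inf and not math.isfinite(e_prop):
            raise ValueError(f"non-finite energy at equilibration step {i}")
        if e_prop - e <= 0 or rng.random() < math.exp(-beta * (e_prop - e)):
            x, e = prop, e_prop
            acc_block += 1
        if (i + 1) % 50 == 0:
            frac = acc_block / 50
            step *= 1.2 if frac > _TARGET_ACCEPTANCE else 1 / 1.2
            acc_block = 0

    positions = np.empty((config.n_steps, dim))
    energies = np.empty(config.n_steps)
    accepted = 0
    for i in range(config.n_steps):
        prop = x + rng.normal(scale=step, size=dim)
        e_prop = potential.energy(prop)
        if e_prop != math.inf and not math.isfinite(e_prop):
            raise ValueError(f"non-finite energy at production step {i}")
        if e_prop - e <= 0 or rng.random() < math.exp(-beta * (e_prop - e)):
            x, e = prop, e_prop
            accepted += 1
        positions[i] = x
        energies[i] = e
    return MCResult(
        positions=positions,
        energies=energies,
        acceptance_fraction=accepted / config.n_steps,
        step_size=step,
    )


def generate_window_samples(
    v1,
    v2,
    schedule: LambdaSchedule,
    config: MCConfig,
    thermo: ThermoState,
    state: State = State.FREE,
) -> list[WindowSamples]:
    """Sample ΔV = V(λ+Δλ) − V(λ) in every window for every replica.

    One independent Metropolis chain is run per (window × replica); no
    configurations are reused across windows.  The per-chain seed is
    spawned deterministically from (config.seed, window index, replica),
    so identical inputs reproduce identical sample sets bit for bit.
    Returns one :class:`WindowSamples` per window per replica.
    """
    if len(schedule) < 2:
        raise ValueError("schedule needs at least two lambda values")
    if getattr(v1, "dim", 1) != getattr(v2, "dim", 1):
        raise ValueError("end-state potentials have different dimensionality")
    lams = schedule.values
    out: list[WindowSamples] = []
    for i in range(schedule.n_windows):
        lam, lam_next = lams[i], lams[i + 1]
        dlam = lam_next - lam
        for rep in range(1, config.n_replicas + 1):
            rng = np.random.default_rng([config.seed, i, rep])
            chain = metropolis_sample(
                MixedPotential(v1, v2, lam), config, thermo, rng=rng
            )
            # ΔV(λ→λ+Δλ; x) = Δλ·(V2(x) − V1(x)), componentwise
            de = np.empty(config.n_steps)
            dw = np.empty(config.n_steps)
            for j, x in enumerate(chain.positions):
                e1, w1 = v1.energy_components(x)
                e2, w2 = v2.energy_components(x)
                de[j] = dlam * (e2 - e1)
                dw[j] = dlam * (w2 - w1)
            out.append(WindowSamples(
                lambda_value=lam,
                delta_lambda=dlam,
                dv_total=de + dw,
                dv_elec=de,
                dv_vdw=dw,
                state=state,
                replica_id=rep,
            ))
    return out


# ---------------------------------------------------------------------------
# Ground-truth oracles
# ---------------------------------------------------------------------------

def analytic_harmonic_dg(
    k1: float, k2: float, dim: int, thermo: ThermoState
) -> float:
    """Exact ΔG between isotropic harmonic wells: (d/2)·kBT·ln(k2/k1)."""
    if k1 <= 0 or k2 <= 0:
        raise ValueError("spring constants must be positive")
    return 0.5 * dim * thermo.kt * math.log(k2 / k1)


@dataclass(frozen=True)
class QuadratureGrid:
    """Integration grid for the direct partition-function ratio."""

    lower: float = -20.0
    upper: float = 20.0
    n: int = 4001

    def __post_init__(self) -> None:
        if self.upper <= self.lower or self.n < 3:
            raise ValueError("invalid quadrature grid")


def quadrature_dg(
    v1,
    v2,
    thermo: ThermoState,
    grid: QuadratureGrid = QuadratureGrid(),
) -> tuple[float, float]:
    """−kBT·ln(Z2/Z1) by direct trapezoidal integration (1-D or 2-D only).

    Returns ``(dg, refinement_error)`` where the error is the change when
    the grid resolution is halved; raises if either Boltzmann integral is
    numerically zero (non-integrable / mis-scaled potential on the grid).
    """
    dim = getattr(v1, "dim", 1)
    if dim > 2:
        raise ValueError("quadrature oracle supports 1-D and 2-D only")

    def log_z(pot, n: int) -> float:
        xs = np.linspace(grid.lower, grid.upper, n)
        if dim == 1:
            log_b = np.array(
                [-thermo.beta * pot.energy(np.array([x])) for x in xs]
            )
        else:
            log_b = np.array([
                [-thermo.beta * pot.energy(np.array([x, y])) for y in xs]
                for x in xs
            ])
        w = np.exp(log_b - log_b.max())
        h = xs[1] - xs[0]
        integral = np.trapezoid(w, dx=h)
        if dim == 2:
            integral = np.trapezoid(integral, dx=h)
        if integral <= 0 or not np.isfinite(integral):
            raise ValueError("Boltzmann integral vanished on the grid")
        return float(log_b.max() + np.log(integral))

    def dg_at(n: int) -> float:
        return -thermo.kt * (log_z(v2, n) - log_z(v1, n))

    full = dg_at(grid.n)
    coarse = dg_at(grid.n // 2 + 1)
    return full, abs(full - coarse)


# ---------------------------------------------------------------------------
# Synthetic two-chain trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChainSpec:
    """One bead chain: chain id and ordered residue names (one bead each)."""

    chain_id: str
    residues: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("chain must have at least one residue")
        object.__setattr__(self, "residues", tuple(self.residues))


@dataclass(frozen=True)
class SyntheticTrajectorySpec:
    """Prescription for a two-chain bead trajectory with known contacts.

    Chain beads sit on a 5 Å-spaced line; each residue of the first
    (peptide-like) chain approaches its partner bead on the second chain
    to ``contact_distance`` during its scheduled frame intervals and sits
    at ``separated_distance`` otherwise, plus isotropic Gaussian noise.
    Intervals are half-open ``[start, end)`` in 1-based frame numbering.
    """

    n_frames: int
    chains: tuple[ChainSpec, ChainSpec]
    contact_schedule: dict[int, tuple[tuple[int, int], ...]] = field(
        default_factory=dict
    )
    noise_sigma: float = 0.0
    contact_distance: float = 4.0
    separated_distance: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not self.contact_distance < self.separated_distance:
            raise ValueError(
                "contact_distance must be smaller than separated_distance"
            )
        sched = {
            int(r): tuple((int(a), int(b)) for a, b in ivals)
            for r, ivals in self.contact_schedule.items()
        }
        n_res = len(self.chains[0].residues)
        for r, ivals in sched.items():
            if not 1 <= r <= n_res:
                raise ValueError(f"scheduled residue {r} outside chain")
            for a, b in ivals:
                if not (1 <= a <= b <= self.n_frames + 1):
                    raise ValueError(
                        f"interval [{a}, {b}) outside [1, {self.n_frames}]"
                    )
        object.__setattr__(self, "contact_schedule", sched)


_BEAD_SPACING = 5.0


def generate_toy_trajectory(spec: SyntheticTrajectorySpec) -> Trajectory:
    """Realize the two-chain bead trajectory described by ``spec``.

    Chain 1 beads lie along x at y=0; chain 2 beads lie along x displaced
    in +y.  Residue i of chain 1 moves to within ``contact_distance`` of
    bead i of chain 2 during its scheduled intervals.  Deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    ch1, ch2 = spec.chains
    n1, n2 = len(ch1.residues), len(ch2.residues)
    n = n1 + n2
    base = np.zeros((n, 3))
    for i in range(n1):
        base[i] = (i * _BEAD_SPACING, 0.0, 0.0)
    for j in range(n2):
        base[n1 + j] = (j * _BEAD_SPACING, spec.separated_distance, 0.0)

    in_contact = np.zeros((spec.n_frames, n1), dtype=bool)
    for r, ivals in spec.contact_schedule.items():
        for a, b in ivals:
            in_contact[a - 1: b - 1, r - 1] = True

    coords = np.repeat(base[None, :, :], spec.n_frames, axis=0)
    for f in range(spec.n_frames):
        for i in range(n1):
            if in_contact[f, i] and i < n2:
                # move bead i toward its chain-2 partner along y
                coords[f, i, 1] = spec.separated_distance - spec.contact_distance
    if spec.noise_sigma > 0:
        coords += rng.normal(scale=spec.noise_sigma, size=coords.shape)

    atoms = make_atom_table(
        names=["CA"] * n,
        resids=list(range(1, n1 + 1)) + list(range(1, n2 + 1)),
        resnames=list(ch1.residues) + list(ch2.residues),
        chains=[ch1.chain_id] * n1 + [ch2.chain_id] * n2,
        elements=["C"] * n,
    )
    return Trajectory(coords, atoms)
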