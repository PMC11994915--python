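"""Free-energy perturbation over a λ-window schedule.

The free-energy change of an alchemical transformation (wild-type potential
V1 → mutant potential V2) is accumulated over a ladder of coupling values
λ ∈ [0, 1], with the mixed potential

    V(λ) = (1 − λ)·V1 + λ·V2.

Each window contributes the Zwanzig exponential average

    ΔG_λ = −kB·T · ln ⟨ exp(−β·[V(λ+Δλ) − V(λ)]) ⟩_λ

sampled in the ensemble of V(λ), and the total is the sum over windows,
ΔG = Σ_λ ΔG_λ.  The relative binding free energy of a mutation is obtained
from a thermodynamic cycle as ΔΔG = ΔG_bound − ΔG_free, where both legs
apply the identical mutation in the receptor-bound complex and in the free
peptide.  Positive ΔΔG means the mutation weakens binding.

The electrostatic / van der Waals decomposition applies the same estimator
to the component perturbation energies collected in the same configurational
ensembles as the full interaction; because exponential averaging is
nonlinear the components do not add exactly, leaving a (small) coupling
term total − elec − vdw.
"""

from __future__ import annotations

import csv
import enum
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp

from .thermo import ThermoState

__all__ = [
    "LambdaSchedule",
    "State",
    "WindowSamples",
    "EnergyComponents",
    "FreeEnergyResult",
    "ThermoCycle",
    "default_lambda_schedule",
    "mixed_potential",
    "window_free_energy",
    "total_free_energy",
    "relative_binding_free_energy",
    "decompose",
    "estimate_free_energy",
    "replica_standard_error",
    "softcore_pair_energy",
    "read_window_samples",
    "write_window_samples",
]

# The 46-window soft-core λ ladder (47 states, densest near the end points
# where atoms appear/vanish).
_DEFAULT_LAMBDAS: tuple[float, ...] = (
    0.00, 0.00001, 0.0001, 0.001, 0.01, 0.02, 0.06, 0.1, 0.14, 0.18,
    0.22, 0.26, 0.30, 0.34, 0.38, 0.42, 0.46, 0.5, 0.54, 0.58,
    0.62, 0.66, 0.7, 0.74, 0.78, 0.82, 0.86, 0.885, 0.89, 0.891,
    0.893, 0.895, 0.898, 0.9, 0.911, 0.913, 0.915, 0.918, 0.92, 0.925,
    0.94, 0.98, 0.99, 0.999, 0.9999, 0.99999, 1.00,
)


class State(str, enum.Enum):
    """Leg of the thermodynamic cycle a sample set belongs to."""

    BOUND = "bound"
    FREE = "free"


@dataclass(frozen=True)
class LambdaSchedule:
    """Ordered ladder of coupling values λ, strictly increasing from 0 to 1."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        object.__setattr__(self, "values", vals)
        if len(vals) < 2:
            raise ValueError("a lambda schedule needs at least two values")
        if vals[0] != 0.0 or vals[-1] != 1.0:
            raise ValueError("schedule must start at 0.0 and end at 1.0")
        arr = np.asarray(vals)
        if not np.all(np.diff(arr) > 0):
            raise ValueError("lambda values must be strictly increasing")
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValueError("lambda values must lie in [0, 1]")

    @property
    def n_windows(self) -> int:
        """Number of λ → λ+Δλ transitions."""
        return len(self.values) - 1

    @property
    def deltas(self) -> tuple[float, ...]:
        return tuple(b - a for a, b in zip(self.values[:-1], self.values[1:]))

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)


def default_lambda_schedule() -> LambdaSchedule:
    """The soft-core 46-window ladder used for all mutation transformations.

    47 λ states spanning 0.00 … 1.00, very finely spaced near both end
    points (Δλ down to 1e-5) so that appearing/vanishing soft-core atoms
    perturb gently, and coarser (Δλ = 0.04) through the middle.
    """
    return LambdaSchedule(_DEFAULT_LAMBDAS)


@dataclass(frozen=True)
class WindowSamples:
    """Perturbation-energy samples for one window, one cycle leg, one replica.

    ``dv_total`` holds samples of V(λ+Δλ; x) − V(λ; x) over configurations x
    drawn at λ; ``dv_elec`` and ``dv_vdw`` are the electrostatic and van der
    Waals parts of the same perturbation evaluated on the same
    configurations.
    """

    lambda_value: float
    delta_lambda: float
    dv_total: np.ndarray
    dv_elec: np.ndarray
    dv_vdw: np.ndarray
    state: State = State.FREE
    replica_id: int = 1

    def __post_init__(self) -> None:
        for name in ("dv_total", "dv_elec", "dv_vdw"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=float)
            )
        n = self.dv_total.size
        if n == 0:
            raise ValueError("window sample set is empty")
        if self.dv_elec.size != n or self.dv_vdw.size != n:
            raise ValueError(
                "dv_total, dv_elec and dv_vdw must have equal length "
                f"(got {n}, {self.dv_elec.size}, {self.dv_vdw.size})"
            )
        if self.replica_id < 1:
            raise ValueError("replica_id must be >= 1")
        object.__setattr__(self, "state", State(self.state))

    @property
    def n_samples(self) -> int:
        return int(self.dv_total.size)


@dataclass(frozen=True)
class EnergyComponents:
    """Electrostatic / van der Waals split of a free-energy change.

    The decomposition is path dependent and the exponential average is
    nonlinear, so the components need not add up to the total; the residual
    is stored as the ``coupling`` term and ``total == elec + vdw + coupling``
    holds identically by construction.
    """

    total: float
    elec: float
    vdw: float
    coupling: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "coupling", self.total - self.elec - self.vdw)


@dataclass(frozen=True)
class FreeEnergyResult:
    """Accumulated ΔG with per-window detail, components and replica spread."""

    per_window: tuple[float, ...]
    total_dg: float
    components: EnergyComponents
    replica_values: tuple[float, ...]
    standard_error: float

    def __post_init__(self) -> None:
        if abs(self.total_dg - math.fsum(self.per_window)) > 1e-9:
            raise ValueError("total_dg must equal the sum of per-window terms")
        if self.standard_error < 0:
            raise ValueError("standard error cannot be negative")


@dataclass(frozen=True)
class ThermoCycle:
    """Thermodynamic-cycle ΔΔG = ΔG_bound − ΔG_free for one mutation.

    The two direct binding legs of the cycle are never simulated; the
    identical alchemical mutation is carried out in the bound complex
    (``dg_bound``) and in the free peptide (``dg_free``) and the cycle
    closes exactly, giving the relative binding free energy as their
    difference.  ``standard_error`` combines the two leg errors in
    quadrature (an explicit convention of this package; per-leg errors
    remain available on the legs).
    """

    dg_bound: FreeEnergyResult
    dg_free: FreeEnergyResult
    ddg: float = field(init=False)
    components: EnergyComponents = field(init=False)
    standard_error: float = field(init=False)

    def __post_init__(self) -> None:
        b, f = self.dg_bound, self.dg_free
        object.__setattr__(self, "ddg", b.total_dg - f.total_dg)
        object.__setattr__(
            self,
            "components",
            EnergyComponents(
                total=b.total_dg - f.total_dg,
                elec=b.components.elec - f.components.elec,
                vdw=b.components.vdw - f.components.vdw,
            ),
        )
        object.__setattr__(
            self,
            "standard_error",
            math.hypot(b.standard_error, f.standard_error),
        )


def mixed_potential(v1: float, v2: float, lam: float) -> float:
    """Linear alchemical mixing V(λ) = (1 − λ)·V1 + λ·V2.

    Raises ``ValueError`` if λ is outside [0, 1].
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    return (1.0 - lam) * v1 + lam * v2


def window_free_energy(
    dv: np.ndarray | Sequence[float] | WindowSamples,
    thermo: ThermoState,
) -> float:
    """Zwanzig exponential-average free energy of one forward window.

    ΔG_λ = −kB·T · ln ⟨exp(−β·ΔV)⟩, evaluated with log-sum-exp so that
    large |β·ΔV| cannot overflow.  Accepts a raw ΔV array or a
    :class:`WindowSamples` (whose ``dv_total`` is used).
    """
    if isinstance(dv, WindowSamples):
        dv = dv.dv_total
    arr = np.asarray(dv, dtype=float)
    if arr.size == 0:
        raise ValueError("window free energy requires at least one sample")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite perturbation energy in sample set")
    # ln⟨exp(−βΔV)⟩ = logsumexp(−βΔV) − ln n
    log_avg = logsumexp(-thermo.beta * arr) - math.log(arr.size)
    return -thermo.kt * float(log_avg)


def total_free_energy(
    window_results: Sequence[float],
    schedule: LambdaSchedule | None = None,
) -> float:
    """Sum of per-window ΔG_λ; ΔG = Σ_λ ΔG_λ.

    If a schedule is given, the number of window results must equal its
    number of transitions (schedule length − 1).
    """
    vals = list(window_results)
    if not vals:
        raise ValueError("no window results to accumulate")
    if schedule is not None and len(vals) != schedule.n_windows:
        raise ValueError(
            f"expected {schedule.n_windows} window results for the schedule, "
            f"got {len(vals)}"
        )
    return math.fsum(vals)


def replica_standard_error(replica_values: Sequence[float]) -> float:
    """Standard error over independent replicas: sd(n−1) / sqrt(n)."""
    vals = np.asarray(list(replica_values), dtype=float)
    if vals.size < 2:
        raise ValueError("standard error requires at least two replicas")
    return float(vals.std(ddof=1) / math.sqrt(vals.size))


#: Windows with fewer samples than this emit a convergence warning.
MIN_SAMPLES_WARN = 50


def _component_dg(
    windows: Sequence[WindowSamples], attr: str, thermo: ThermoState
) -> float:
    return math.fsum(
        window_free_energy(getattr(w, attr), thermo) for w in windows
    )


def decompose(
    samples_per_window: Sequence[WindowSamples], thermo: ThermoState
) -> EnergyComponents:
    """Component free energies from one replica's windows.

    The elec (resp. vdW) term applies the Zwanzig estimator to ``dv_elec``
    (resp. ``dv_vdw``) in the same sample ensembles as the total; the
    coupling term closes the identity total = elec + vdw + coupling.
    """
    if not samples_per_window:
        raise ValueError("no windows supplied")
    return EnergyComponents(
        total=_component_dg(samples_per_window, "dv_total", thermo),
        elec=_component_dg(samples_per_window, "dv_elec", thermo),
        vdw=_component_dg(samples_per_window, "dv_vdw", thermo),
    )


def estimate_free_energy(
    windows: Iterable[WindowSamples],
    thermo: ThermoState,
    schedule: LambdaSchedule | None = None,
    min_samples: int = MIN_SAMPLES_WARN,
) -> FreeEnergyResult:
    """Full multi-replica estimate for one leg of the thermodynamic cycle.

    Windows are grouped by replica; each replica must cover the same set of
    λ values.  Per-window ΔG_λ is averaged across replicas, the total is
    the sum of those averages (identically the mean of the per-replica
    totals), and the standard error is taken over the per-replica totals.
    Components are estimated the same way from ``dv_elec`` / ``dv_vdw``.
    """
    by_replica: dict[int, list[WindowSamples]] = {}
    for w in windows:
        by_replica.setdefault(w.replica_id, []).append(w)
    if not by_replica:
        raise ValueError("no window samples supplied")

    lam_sets = {
        rid: tuple(sorted(w.lambda_value for w in ws))
        for rid, ws in by_replica.items()
    }
    if len(set(lam_sets.values())) != 1:
        raise ValueError("replicas cover different lambda windows")
    for ws in by_replica.values():
        ws.sort(key=lambda w: w.lambda_value)
    n_win = len(next(iter(by_replica.values())))
    if schedule is not None and n_win != schedule.n_windows:
        raise ValueError(
            f"samples cover {n_win} windows but the schedule has "
            f"{schedule.n_windows}"
        )
    starving = sorted(
        {w.lambda_value for ws in by_replica.values() for w in ws
         if w.n_samples < min_samples}
    )
    if starving:
        warnings.warn(
            f"windows at lambda={starving} have fewer than {min_samples} "
            "samples; the exponential average may be poorly converged",
            RuntimeWarning,
            stacklevel=2,
        )

    # per-replica per-window ΔG for each component
    per_rep_win = {
        rid: [window_free_energy(w, thermo) for w in ws]
        for rid, ws in by_replica.items()
    }
    rep_ids = sorted(per_rep_win)
    per_window = tuple(
        float(np.mean([per_rep_win[rid][i] for rid in rep_ids]))
        for i in range(n_win)
    )
    replica_totals = tuple(math.fsum(per_rep_win[rid]) for rid in rep_ids)
    total = math.fsum(per_window)

    elec = float(np.mean([
        _component_dg(by_replica[rid], "dv_elec", thermo) for rid in rep_ids
    ]))
    vdw = float(np.mean([
        _component_dg(by_replica[rid], "dv_vdw", thermo) for rid in rep_ids
    ]))

    se = replica_standard_error(replica_totals) if len(rep_ids) >= 2 else 0.0
    return FreeEnergyResult(
        per_window=per_window,
        total_dg=total,
        components=EnergyComponents(total=total, elec=elec, vdw=vdw),
        replica_values=replica_totals,
        standard_error=se,
    )


def relative_binding_free_energy(
    dg_bound: FreeEnergyResult | float,
    dg_free: FreeEnergyResult | float,
) -> ThermoCycle:
    """Close the thermodynamic cycle: ΔΔG = ΔG_bound − ΔG_free.

    Positive ΔΔG ⇒ the mutation weakens binding; negative ⇒ enhances.
    Bare floats are wrapped as single-window, zero-error results so simple
    arithmetic uses the same code path as full estimates.
    """
    def as_result(x):
        if isinstance(x, FreeEnergyResult):
            return x
        x = float(x)
        return FreeEnergyResult(
            per_window=(x,),
            total_dg=x,
            components=EnergyComponents(total=x, elec=0.0, vdw=x),
            replica_values=(x,),
            standard_error=0.0,
        )

    return ThermoCycle(dg_bound=as_result(dg_bound), dg_free=as_result(dg_free))


# ---------------------------------------------------------------------------
# Soft-core pair potential
# ---------------------------------------------------------------------------

#: Coulomb constant in kcal·Å/(mol·e²).
COULOMB_KCAL_A = 332.0637


def softcore_pair_energy(
    r: float,
    lam: float,
    sigma: float,
    epsilon: float,
    alpha: float = 0.5,
    charge_product: float = 0.0,
    coulomb_constant: float = COULOMB_KCAL_A,
) -> EnergyComponents:
    """Soft-core Lennard-Jones + linearly scaled Coulomb pair energy.

    Beutler-style vdW soft-core with λ-power 1:

        V_vdw(r, λ) = (1−λ)·4ε·[ (1/(αλ + (r/σ)⁶))² − 1/(αλ + (r/σ)⁶) ]

    and electrostatics scaled linearly, V_elec = (1−λ)·C·q₁q₂/r.  At λ=0
    this is exactly the standard LJ + Coulomb pair energy; at λ=1 the pair
    is fully decoupled (zero); for λ>0 the vdW term stays bounded as r→0,
    removing the singularity of vanishing atoms.
    """
    if r <= 0:
        raise ValueError(f"pair distance must be positive, got {r}")
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    if alpha < 0:
        raise ValueError(f"soft-core alpha must be >= 0, got {alpha}")
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    s6 = alpha * lam + (r / sigma) ** 6
    vdw = (1.0 - lam) * 4.0 * epsilon * (s6 ** -2 - s6 ** -1)
    elec = (1.0 - lam) * coulomb_constant * charge_product / r
    return EnergyComponents(total=vdw + elec, elec=elec, vdw=vdw)


# ---------------------------------------------------------------------------
# Window-sample tabular format
# ---------------------------------------------------------------------------

_TABLE_HEADER = [
    "lambda", "delta_lambda", "component", "state", "replica",
    "dv_kcal_per_mol",
]


def write_window_samples(
    windows: Iterable[WindowSamples], path: str | Path
) -> None:
    """Write windows as a long-format CSV, one row per sample per component.

    Floats are written with ``repr`` so that a read → write cycle
    reproduces the file byte for byte.
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_TABLE_HEADER)
        for w in windows:
            for comp, arr in (
                ("total", w.dv_total), ("elec", w.dv_elec), ("vdw", w.dv_vdw)
            ):
                for v in arr:
                    writer.writerow([
                        repr(w.lambda_value), repr(w.delta_lambda), comp,
                        w.state.value, w.replica_id, repr(float(v)),
                    ])


def read_window_samples(path: str | Path) -> list[WindowSamples]:
    """Read the tabular window-sample format back into WindowSamples.

    Rows are grouped by (λ, Δλ, state, replica); each group must contain
    equal-length total/elec/vdw sample series.
    """
    path = Path(path)
    groups: dict[tuple, dict[str, list[float]]] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != _TABLE_HEADER:
            raise ValueError(
                f"{path}: unexpected header {header!r}; "
                f"expected {_TABLE_HEADER!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                lam, dlam, comp, state, rep, dv = row
                key = (float(lam), float(dlam), state, int(rep))
                groups.setdefault(
                    key, {"total": [], "elec": [], "vdw": []}
                )[comp].append(float(dv))
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}:{lineno}: bad row {row!r}") from exc
    out = []
    for (lam, dlam, state, rep), comps in sorted(groups.items()):
        out.append(WindowSamples(
            lambda_value=lam, delta_lambda=dlam,
            dv_total=np.array(comps["total"]),
            dv_elec=np.array(comps["elec"]),
            dv_vdw=np.array(comps["vdw"]),
            state=State(state), replica_id=rep,
        ))
    return out
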