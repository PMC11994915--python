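"""Mutation bookkeeping for sulfopeptide scanning workflows.

Models the disulfated pentapeptide growth factor PSK (sY-I-sY-T-Q, where
sY is O-sulfotyrosine) and its variants: parsing mutation labels such as
``"Q5K"``, ``"sY1Y"`` (desulfation) or ``"I2T+T4I"`` (compound), applying
them, computing average molecular weights, converting dissociation
constants to experimental ΔΔG, classifying mutations as binding-enhancing
/ neutral / weakening relative to their replica standard error, and
assembling scan reports.
"""

from __future__ import annotations

import enum
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .alchemy import ThermoCycle
from .thermo import ThermoState

__all__ = [
    "Residue",
    "PeptideSpec",
    "SiteMutation",
    "MutationSpec",
    "MutationFormatError",
    "MutationSiteError",
    "MutationMismatchError",
    "KdPair",
    "Classification",
    "ScanRow",
    "WT_PSK",
    "parse_mutation",
    "apply_mutation",
    "average_mass",
    "ddg_from_kd",
    "classify",
    "fep_budget",
    "relative_root_growth",
    "build_scan_report",
    "scan_report_frame",
    "write_scan_report",
]

# Average residue (amino-acid minus water) masses, Da.
RESIDUE_MASSES: dict[str, float] = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MASS = 18.0153
#: Average mass of the SO3 group added by tyrosine O-sulfation, Da.
SULFATION_MASS = 80.0632


class MutationFormatError(ValueError):
    """Mutation label does not match the <wild><site><target> grammar."""


class MutationSiteError(ValueError):
    """Mutation site outside the peptide."""


class MutationMismatchError(ValueError):
    """Stated wild-type residue disagrees with the peptide."""


@dataclass(frozen=True)
class Residue:
    """One peptide residue: one-letter code plus sulfation flag."""

    code: str
    sulfated: bool = False

    def __post_init__(self) -> None:
        if self.code not in RESIDUE_MASSES:
            raise ValueError(f"unknown residue code {self.code!r}")
        if self.sulfated and self.code != "Y":
            raise ValueError("sulfation is only defined on tyrosine")

    @property
    def label(self) -> str:
        return ("s" + self.code) if self.sulfated else self.code

    @property
    def mass(self) -> float:
        m = RESIDUE_MASSES[self.code]
        return m + SULFATION_MASS if self.sulfated else m


def _residue_from_code(code: str) -> Residue:
    if code == "sY":
        return Residue("Y", sulfated=True)
    return Residue(code)


@dataclass(frozen=True)
class PeptideSpec:
    """Ordered peptide with free amine/acid termini; positions are 1-based."""

    residues: tuple[Residue, ...]

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("peptide must have at least one residue")
        object.__setattr__(self, "residues", tuple(self.residues))

    @classmethod
    def from_codes(cls, codes: Sequence[str]) -> "PeptideSpec":
        """Build from codes like ``["sY", "I", "sY", "T", "Q"]``."""
        return cls(tuple(_residue_from_code(c) for c in codes))

    @property
    def sequence(self) -> str:
        return "-".join(r.label for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)


#: Wild-type phytosulfokine: disulfated pentapeptide sY-I-sY-T-Q.
WT_PSK = PeptideSpec.from_codes(["sY", "I", "sY", "T", "Q"])


@dataclass(frozen=True)
class SiteMutation:
    wild: str
    site: int
    target: str

    @property
    def label(self) -> str:
        return f"{self.wild}{self.site}{self.target}"


@dataclass(frozen=True)
class MutationSpec:
    """One or more simultaneous site substitutions."""

    sites: tuple[SiteMutation, ...]

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("mutation spec must contain at least one site")
        seen = [s.site for s in self.sites]
        if len(set(seen)) != len(seen):
            raise ValueError(f"duplicate sites in compound mutation: {seen}")

    @property
    def label(self) -> str:
        return "+".join(s.label for s in self.sites)

    @property
    def is_identity(self) -> bool:
        return all(s.wild == s.target for s in self.sites)


_SITE_RE = re.compile(r"^(sY|[A-Z])([0-9]+)(sY|[A-Z])$")


def parse_mutation(
    label: str, peptide: PeptideSpec | None = None
) -> MutationSpec:
    """Parse ``<wild><site><target>[+…]`` labels, e.g. Q5K, sY1Y, I2T+T4I.

    ``sY`` is recognised as the two-character sulfotyrosine code on either
    side.  If a peptide is supplied the site range and stated wild types
    are validated against it, raising :class:`MutationSiteError` or
    :class:`MutationMismatchError` respectively.
    """
    sites = []
    for part in label.strip().split("+"):
        m = _SITE_RE.match(part.strip())
        if not m:
            raise MutationFormatError(
                f"malformed mutation label {part!r} "
                "(expected <wild><site><target>, e.g. Q5K or sY1Y)"
            )
        wild, site, target = m.group(1), int(m.group(2)), m.group(3)
        if wild not in RESIDUE_MASSES and wild != "sY":
            raise MutationFormatError(f"unknown wild-type code {wild!r}")
        if target not in RESIDUE_MASSES and target != "sY":
            raise MutationFormatError(f"unknown target code {target!r}")
        sites.append(SiteMutation(wild, site, target))
    spec = MutationSpec(tuple(sites))
    if peptide is not None:
        _validate(spec, peptide)
    return spec


def _validate(spec: MutationSpec, peptide: PeptideSpec) -> None:
    for s in spec.sites:
        if not 1 <= s.site <= len(peptide):
            raise MutationSiteError(
                f"site {s.site} outside peptide of length {len(peptide)}"
            )
        actual = peptide.residues[s.site - 1].label
        if actual != s.wild:
            raise MutationMismatchError(
                f"position {s.site} is {actual}, not {s.wild}"
            )


def apply_mutation(peptide: PeptideSpec, spec: MutationSpec) -> PeptideSpec:
    """Apply all site substitutions simultaneously; returns a new peptide.

    Desulfation (sY → Y) and sulfation (Y → sY) are modification-flag
    changes handled by the same path as identity changes.
    """
    _validate(spec, peptide)
    residues = list(peptide.residues)
    for s in spec.sites:
        residues[s.site - 1] = _residue_from_code(s.target)
    return PeptideSpec(tuple(residues))


def average_mass(peptide: PeptideSpec) -> float:
    """Average molecular weight in Da.

    Sum of average residue masses, plus one water for the free termini,
    plus 80.06 Da of SO3 per sulfated tyrosine (already folded into the
    residue masses).
    """
    return math.fsum(r.mass for r in peptide.residues) + WATER_MASS


# ---------------------------------------------------------------------------
# Experimental ΔΔG, classification, bookkeeping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KdPair:
    """Wild-type and mutant dissociation constants (same unit, any unit)."""

    kd_wt: float
    kd_mut: float

    def __post_init__(self) -> None:
        if self.kd_wt <= 0 or self.kd_mut <= 0:
            raise ValueError("dissociation constants must be positive")


def ddg_from_kd(pair: KdPair, thermo: ThermoState) -> float:
    """Experimental relative binding free energy from Kd measurements.

    ΔΔG_exp = −kB·T·ln(Kd_wt / Kd_mut); only the ratio enters, so the Kd
    unit cancels.  Positive values mean the mutant binds weaker.
    """
    return -thermo.kt * math.log(pair.kd_wt / pair.kd_mut)


class Classification(str, enum.Enum):
    ENHANCING = "enhancing"
    NEUTRAL = "neutral"
    WEAKENING = "weakening"


def classify(ddg: float, se: float) -> Classification:
    """Sign call for a mutation using the replica SE as neutrality band.

    enhancing if ddg + se < 0, weakening if ddg − se > 0, else neutral —
    i.e. a mutation is only called when its error bar clears zero.
    """
    if se < 0:
        raise ValueError("standard error cannot be negative")
    if ddg + se < 0:
        return Classification.ENHANCING
    if ddg - se > 0:
        return Classification.WEAKENING
    return Classification.NEUTRAL


def fep_budget(per_run_ns: float, n_replicas: int, n_states: int) -> float:
    """Total sampling budget of one mutation: per-run ns × replicas × states.

    With the production defaults (18.4 ns per run, 6 replicas, bound +
    free states) this is 220.8 ns per mutation.
    """
    if per_run_ns <= 0 or n_replicas <= 0 or n_states <= 0:
        raise ValueError("all budget factors must be positive")
    return per_run_ns * n_replicas * n_states


def relative_root_growth(
    treated_lengths: Sequence[float], control_lengths: Sequence[float]
) -> float:
    """Relative root growth in percent: 100 × mean(treated)/mean(control)."""
    if len(treated_lengths) == 0 or len(control_lengths) == 0:
        raise ValueError("length lists must be non-empty")
    control_mean = math.fsum(control_lengths) / len(control_lengths)
    if control_mean <= 0:
        raise ValueError("control mean length must be positive")
    treated_mean = math.fsum(treated_lengths) / len(treated_lengths)
    return 100.0 * treated_mean / control_mean


# ---------------------------------------------------------------------------
# Scan reports
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScanRow:
    """One mutation's line in the scan report."""

    mutation: str
    ddg: float
    ddg_elec: float
    ddg_vdw: float
    coupling: float
    se: float
    classification: Classification = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "classification", classify(self.ddg, self.se)
        )


def build_scan_report(
    cycles: Sequence[ThermoCycle], labels: Sequence[str]
) -> list[ScanRow]:
    """Turn thermodynamic cycles into classified report rows, input order."""
    if len(cycles) != len(labels):
        raise ValueError(
            f"{len(labels)} labels but {len(cycles)} results"
        )
    rows = []
    for label, cyc in zip(labels, cycles):
        rows.append(ScanRow(
            mutation=label,
            ddg=cyc.ddg,
            ddg_elec=cyc.components.elec,
            ddg_vdw=cyc.components.vdw,
            coupling=cyc.components.coupling,
            se=cyc.standard_error,
        ))
    return rows


_REPORT_COLUMNS = [
    "mutation", "ddg", "ddg_elec", "ddg_vdw", "coupling", "se", "class",
]


def scan_report_frame(rows: Sequence[ScanRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mutation": r.mutation,
                "ddg": r.ddg,
                "ddg_elec": r.ddg_elec,
                "ddg_vdw": r.ddg_vdw,
                "coupling": r.coupling,
                "se": r.se,
                "class": r.classification.value,
            }
            for r in rows
        ],
        columns=_REPORT_COLUMNS,
    )


def write_scan_report(
    rows: Sequence[ScanRow], path: str | Path, fmt: str | None = None
) -> None:
    """Write rows as CSV or JSON (format inferred from the suffix)."""
    path = Path(path)
    fmt = fmt or ("json" if path.suffix == ".json" else "csv")
    frame = scan_report_frame(rows)
    if fmt == "csv":
        frame.to_csv(path, index=False)
    elif fmt == "json":
        path.write_text(
            json.dumps(frame.to_dict(orient="records"), indent=1) + "\n"
        )
    else:
        raise ValueError(f"unknown report format {fmt!r}")


def read_scan_report(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".json":
        return pd.DataFrame(
            json.loads(path.read_text()), columns=_REPORT_COLUMNS
        )
    return pd.read_csv(path)
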