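"""Physicochemical characterization of mature peptides.

Tick defensins are small (~4 kDa) cationic peptides whose six cysteines
form three disulfide bridges with canonical C1-C4, C2-C5, C3-C6
connectivity.  Oxidation of each bridge removes two hydrogen atoms, so the
mass of the folded peptide is the reduced-chain mass minus ``2 * m(H)`` per
bridge.  This module computes average and monoisotopic masses with that
correction, Henderson-Hasselbalch net charge, and the molar-to-mass
concentration conversion used in MIC reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.SeqUtils import molecular_weight

__all__ = [
    "PeptideSpec",
    "MassResult",
    "average_mass",
    "monoisotopic_mass",
    "net_charge",
    "molar_to_mass_conc",
    "canonical_connectivity",
]

# Average and monoisotopic masses of a hydrogen atom (Da).
_H_AVG = 1.00794
_H_MONO = 1.007825

_AA20 = set("ACDEFGHIKLMNPQRSTVWY")

# Classic textbook pKa set (Lehninger-style termini, EMBOSS-like side
# chains).  Any standard table satisfies the cationicity contract; strong
# termini pKa values keep uncharged homopolymers neutral at pH 7.
PKA = {
    "Nterm": 9.6,
    "Cterm": 2.35,
    "K": 10.5,
    "R": 12.5,
    "H": 6.5,
    "D": 3.9,
    "E": 4.1,
    "C": 8.5,
    "Y": 10.1,
}
_BASIC = ("K", "R", "H")
_ACIDIC = ("D", "E", "C", "Y")


@dataclass(frozen=True)
class PeptideSpec:
    """A mature peptide with a declared number of disulfide bridges."""

    sequence: str
    n_disulfides: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError("empty peptide sequence")
        bad = set(seq) - _AA20
        if bad:
            raise ValueError(f"non-standard residue symbols: {sorted(bad)}")
        if self.n_disulfides < 0:
            raise ValueError("n_disulfides must be >= 0")
        if 2 * self.n_disulfides > seq.count("C"):
            raise ValueError(
                f"{self.n_disulfides} bridges need {2 * self.n_disulfides} Cys, "
                f"sequence has {seq.count('C')}"
            )
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class MassResult:
    average_mass: float
    monoisotopic_mass: float
    disulfide_correction: float

    @property
    def average_mass_da(self) -> int:
        """Average oxidized mass rounded to the nearest dalton (report form)."""
        return round(self.average_mass)


def _masses(spec: PeptideSpec) -> tuple[float, float]:
    avg = molecular_weight(spec.sequence, seq_type="protein")
    mono = molecular_weight(spec.sequence, seq_type="protein", monoisotopic=True)
    return avg, mono


def average_mass(spec: PeptideSpec) -> MassResult:
    """Average (and monoisotopic) mass of the oxidized peptide.

    Sum of average residue masses plus one water, minus 2 H per disulfide
    bridge.  ``MassResult.average_mass_da`` gives the nearest-dalton report
    value.
    """
    avg, mono = _masses(spec)
    corr = 2 * spec.n_disulfides
    return MassResult(
        average_mass=avg - corr * _H_AVG,
        monoisotopic_mass=mono - corr * _H_MONO,
        disulfide_correction=-corr * _H_AVG,
    )


def monoisotopic_mass(spec: PeptideSpec) -> float:
    """Monoisotopic mass of the oxidized peptide in Da."""
    return average_mass(spec).monoisotopic_mass


def net_charge(sequence: str, pH: float = 7.0) -> float:
    """Henderson-Hasselbalch net charge at the given pH.

    Sums the fractional charge of the termini and every ionizable side
    chain (K, R, H positive; D, E, C, Y negative) using the module's
    documented pKa table (``PKA``).
    """
    if not 0 < pH < 14:
        raise ValueError("pH must lie in (0, 14)")
    seq = sequence.upper()
    charge = 1.0 / (1.0 + 10 ** (pH - PKA["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (PKA["Cterm"] - pH))
    for aa in seq:
        if aa in _BASIC:
            charge += 1.0 / (1.0 + 10 ** (pH - PKA[aa]))
        elif aa in _ACIDIC:
            charge -= 1.0 / (1.0 + 10 ** (PKA[aa] - pH))
    return charge


def molar_to_mass_conc(concentration_um: float, mass_da: float) -> float:
    """Convert µM to µg/mL for a peptide of the given mass.

    µg/mL = µM * Da * 1e-3 (1 µmol/L of a 1000 Da compound is 1 mg/L).
    """
    if concentration_um < 0 or mass_da < 0:
        raise ValueError("concentration and mass must be non-negative")
    return concentration_um * mass_da * 1e-3


def canonical_connectivity(
    cys_positions: "list[int] | tuple[int, ...]",
) -> list[tuple[int, int]]:
    """Canonical defensin disulfide pairing C1-C4, C2-C5, C3-C6.

    ``cys_positions`` must be the six cysteine residue indices in strictly
    increasing order (1-based by convention, but any consistent indexing
    works).
    """
    pos = list(cys_positions)
    if len(pos) != 6:
        raise ValueError(f"need exactly 6 cysteine positions, got {len(pos)}")
    if any(b <= a for a, b in zip(pos, pos[1:])):
        raise ValueError("cysteine positions must be strictly increasing")
    return [(pos[0], pos[3]), (pos[1], pos[4]), (pos[2], pos[5])]
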