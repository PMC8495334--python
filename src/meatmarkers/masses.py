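"""Monoisotopic mass arithmetic for peptides, precursors and b/y fragment ions.

Masses follow the standard monoisotopic convention used by targeted-proteomics
software: a peptide's neutral mass is the sum of its residue masses plus one
water; an ``n``-fold protonated ion has m/z ``(M + n*m_H+)/n``.  y-ions retain
the C-terminal residues plus water, b-ions the N-terminal residues without it.
Fixed and variable modifications (carbamidomethyl-Cys, Met oxidation, ...) add
their delta mass to the residue they sit on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "ResidueMassTable",
    "Modification",
    "ModifiedPeptide",
    "CARBAMIDOMETHYL",
    "OXIDATION_M",
    "DEFAULT_TABLE",
    "peptide_neutral_mass",
    "precursor_mz",
    "fragment_mz",
    "annotate_fragment",
    "apply_fixed_modifications",
    "AlphabetError",
]

# Monoisotopic residue masses (Da), i.e. amino-acid masses minus water.
_STD_RESIDUE_MASS = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

WATER_MONO = 18.010565
PROTON_MONO = 1.007276


class AlphabetError(ValueError):
    """Raised when a sequence contains a character with no defined mass."""


@dataclass(frozen=True)
class ResidueMassTable:
    """Monoisotopic residue masses plus the water and proton constants."""

    residue_mass: dict[str, float] = field(
        default_factory=lambda: dict(_STD_RESIDUE_MASS)
    )
    water_mass: float = WATER_MONO
    proton_mass: float = PROTON_MONO

    def mass_of(self, residue: str, position: int | None = None) -> float:
        try:
            return self.residue_mass[residue]
        except KeyError:
            where = "" if position is None else f" at position {position}"
            raise AlphabetError(
                f"no monoisotopic mass defined for residue {residue!r}{where}"
            ) from None


DEFAULT_TABLE = ResidueMassTable()


@dataclass(frozen=True)
class Modification:
    """A fixed or variable mass modification on a residue or terminus."""

    name: str
    targets: frozenset[str]
    delta_mass: float
    fixed: bool = True

    def applies_to(self, residue: str) -> bool:
        return residue in self.targets


#: Iodoacetamide alkylation of cysteine — the usual fixed modification.
CARBAMIDOMETHYL = Modification("Carbamidomethyl", frozenset("C"), 57.02146, fixed=True)
#: Methionine oxidation — the usual variable modification.
OXIDATION_M = Modification("Oxidation", frozenset("M"), 15.99491, fixed=False)


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide sequence with positioned modifications.

    Positions are 1-based into ``sequence``; each modification's target set
    must include the residue it sits on.
    """

    sequence: str
    mods: tuple[tuple[int, Modification], ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        for pos, mod in self.mods:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(
                    f"modification position {pos} outside 1..{len(self.sequence)}"
                )
            residue = self.sequence[pos - 1]
            if not mod.applies_to(residue):
                raise ValueError(
                    f"{mod.name} does not target residue {residue!r} at {pos}"
                )

    def mod_delta_at(self, position: int) -> float:
        """Summed modification delta on the 1-based position."""
        return sum(m.delta_mass for p, m in self.mods if p == position)


def apply_fixed_modifications(
    sequence: str, mods: Iterable[Modification] = (CARBAMIDOMETHYL,)
) -> ModifiedPeptide:
    """Attach every fixed modification to each residue it targets."""
    placed = []
    for mod in mods:
        if not mod.fixed:
            continue
        for i, residue in enumerate(sequence, start=1):
            if mod.applies_to(residue):
                placed.append((i, mod))
    return ModifiedPeptide(sequence, tuple(sorted(placed, key=lambda t: t[0])))


def _residue_masses(p: ModifiedPeptide, table: ResidueMassTable) -> list[float]:
    return [
        table.mass_of(res, i) + p.mod_delta_at(i)
        for i, res in enumerate(p.sequence, start=1)
    ]


def peptide_neutral_mass(
    p: ModifiedPeptide, table: ResidueMassTable = DEFAULT_TABLE
) -> float:
    """Neutral monoisotopic mass: residues + modifications + one water."""
    return sum(_residue_masses(p, table)) + table.water_mass


def precursor_mz(
    p: ModifiedPeptide, charge: int, table: ResidueMassTable = DEFAULT_TABLE
) -> float:
    """m/z of the ``charge``-fold protonated intact peptide."""
    if charge < 1:
        raise ValueError(f"precursor charge must be >= 1, got {charge}")
    return (peptide_neutral_mass(p, table) + charge * table.proton_mass) / charge


def fragment_mz(
    p: ModifiedPeptide,
    series: str,
    index: int,
    charge: int = 1,
    table: ResidueMassTable = DEFAULT_TABLE,
) -> float:
    """m/z of the b- or y-ion with ``index`` residues at the given charge.

    ``y_n`` keeps the last ``n`` residues plus water; ``b_n`` the first ``n``
    residues without water.  Valid indices run 1..len-1.
    """
    if series not in ("b", "y"):
        raise ValueError(f"ion series must be 'b' or 'y', got {series!r}")
    if charge < 1:
        raise ValueError(f"fragment charge must be >= 1, got {charge}")
    n = len(p.sequence)
    if not 1 <= index < n:
        raise ValueError(f"fragment index {index} outside 1..{n - 1}")
    masses = _residue_masses(p, table)
    if series == "y":
        neutral = sum(masses[n - index:]) + table.water_mass
    else:
        neutral = sum(masses[:index])
    return (neutral + charge * table.proton_mass) / charge


def annotate_fragment(
    p: ModifiedPeptide,
    observed_mz: float,
    tol: float = 0.02,
    charges: Sequence[int] = (1,),
    table: ResidueMassTable = DEFAULT_TABLE,
) -> list[tuple[str, int, int, float]]:
    """All b/y ions of ``p`` within ``tol`` of ``observed_mz``.

    Returns ``(series, index, charge, delta)`` tuples sorted by ``|delta|``
    where ``delta = theoretical - observed``; empty list when nothing matches.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    hits = []
    for series in ("b", "y"):
        for index in range(1, len(p.sequence)):
            for charge in charges:
                delta = fragment_mz(p, series, index, charge, table) - observed_mz
                if abs(delta) <= tol:
                    hits.append((series, index, charge, delta))
    hits.sort(key=lambda h: abs(h[3]))
    return hits
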