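"""Cross-species uniqueness screening of tryptic peptides.

A marker ("species-specific", proteotypic) peptide is one whose sequence occurs
in exactly one species' digested proteome and survives the assay-suitability
filter: 9-17 residues, no missed cleavages, tryptic termini, no oxidation-prone
residues.  Because triple-quadrupole instruments cannot distinguish the
isobaric residues leucine and isoleucine, uniqueness is assessed on I/L-merged
keys by default — a peptide whose I/L twin exists in another species is not a
marker.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .digest import Peptide, Protein

__all__ = [
    "peptide_key",
    "PeptideIndex",
    "MarkerFilter",
    "build_index",
    "find_species_specific",
    "specificity_report",
    "write_marker_table",
]


def peptide_key(sequence: str, equate_il: bool = True) -> str:
    """Canonical uniqueness key: uppercase, with I folded onto L if requested."""
    key = sequence.upper()
    if equate_il:
        key = key.replace("I", "L")
    return key


@dataclass
class PeptideIndex:
    """Map from canonical peptide key to the (species, protein) pairs holding it."""

    equate_il: bool
    occurrences: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    peptides: dict[str, list[Peptide]] = field(default_factory=dict)

    @property
    def species(self) -> frozenset[str]:
        return frozenset(sp for occ in self.occurrences.values() for sp, _ in occ)

    def species_of(self, key: str) -> frozenset[str]:
        return frozenset(sp for sp, _ in self.occurrences.get(key, ()))


@dataclass(frozen=True)
class MarkerFilter:
    """Assay-suitability gates applied on top of cross-species uniqueness.

    Defaults mirror targeted-assay practice for quadrupole instruments: length
    9-17, fully cleaved, tryptic at both ends, no methionine (oxidation makes
    the response unstable).  Cysteine is allowed because it is carried
    carbamidomethylated.
    """

    min_len: int = 9
    max_len: int = 17
    max_missed_for_marker: int = 0
    require_tryptic_termini: bool = True
    exclude_residues: frozenset[str] = frozenset("M")

    def __post_init__(self) -> None:
        if not 1 <= self.min_len <= self.max_len:
            raise ValueError("need 1 <= min_len <= max_len")

    def passes(self, peptide: Peptide) -> bool:
        if peptide.has_ambiguous:
            return False
        if not self.min_len <= len(peptide) <= self.max_len:
            return False
        if peptide.missed_cleavages > self.max_missed_for_marker:
            return False
        if self.require_tryptic_termini and not (
            peptide.nterm_tryptic and peptide.cterm_tryptic
        ):
            return False
        if set(peptide.sequence) & self.exclude_residues:
            return False
        return True


def build_index(peptides: Iterable[Peptide], equate_il: bool = True) -> PeptideIndex:
    """Index digested peptides from >= 2 species under the canonical key."""
    index = PeptideIndex(equate_il=equate_il)
    for pep in peptides:
        key = peptide_key(pep.sequence, equate_il)
        index.occurrences.setdefault(key, set()).add((pep.species, pep.protein_id))
        index.peptides.setdefault(key, []).append(pep)
    if len(index.species) < 2:
        raise ValueError(
            "uniqueness screening needs peptides from at least 2 species"
        )
    return index


def _occurs_as_substring(
    key: str, proteins: Iterable[Protein], equate_il: bool
) -> bool:
    return any(key in peptide_key(p.sequence, equate_il) for p in proteins)


def find_species_specific(
    index: PeptideIndex,
    species: str,
    marker_filter: MarkerFilter = MarkerFilter(),
    strict_proteins: Mapping[str, Iterable[Protein]] | None = None,
    rank_intensities: Mapping[str, float] | None = None,
) -> list[Peptide]:
    """Marker peptides unique to ``species``, one per canonical key.

    A key qualifies when its occurrence set names exactly the query species and
    at least one of its peptide records passes ``marker_filter``.  With
    ``strict_proteins`` (map species -> proteins), a candidate is additionally
    rejected if its key occurs as a substring anywhere in another species'
    proteome — guarding against homologous context missed by tryptic-space
    comparison.  Output is sorted by sequence, or by descending observed
    response first when an empirical ``rank_intensities`` table (sequence ->
    intensity) is supplied — abundance cannot be predicted in silico, so
    ranking is only ever empirical.
    """
    if species not in index.species:
        raise KeyError(f"species {species!r} not present in index")
    markers = []
    for key, occ in index.occurrences.items():
        if {sp for sp, _ in occ} != {species}:
            continue
        passing = [p for p in index.peptides[key] if marker_filter.passes(p)]
        if not passing:
            continue
        if strict_proteins is not None:
            others = (
                prot
                for sp, prots in strict_proteins.items()
                if sp != species
                for prot in prots
            )
            if _occurs_as_substring(key, others, index.equate_il):
                continue
        markers.append(min(passing, key=lambda p: (p.sequence, p.protein_id, p.start)))
    if rank_intensities is not None:
        markers.sort(
            key=lambda p: (-rank_intensities.get(p.sequence, 0.0), p.sequence)
        )
    else:
        markers.sort(key=lambda p: p.sequence)
    return markers


def specificity_report(index: PeptideIndex, sequence: str) -> pd.DataFrame:
    """Per-species count of proteins containing the peptide; zero rows included."""
    key = peptide_key(sequence, index.equate_il)
    counts: dict[str, int] = defaultdict(int)
    for sp, _pid in index.occurrences.get(key, ()):
        counts[sp] += 1
    rows = [
        {"species": sp, "n_proteins": counts.get(sp, 0)}
        for sp in sorted(index.species)
    ]
    return pd.DataFrame(rows, columns=["species", "n_proteins"])


def write_marker_table(markers: Iterable[Peptide], path: str | Path) -> None:
    """Write the marker list as CSV (species, sequence, provenance, flags)."""
    rows = [
        {
            "species": m.species,
            "sequence": m.sequence,
            "protein_id": m.protein_id,
            "length": len(m),
            "missed_cleavages": m.missed_cleavages,
            "nterm_tryptic": m.nterm_tryptic,
            "cterm_tryptic": m.cterm_tryptic,
        }
        for m in markers
    ]
    columns = [
        "species", "sequence", "protein_id", "length",
        "missed_cleavages", "nterm_tryptic", "cterm_tryptic",
    ]
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
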