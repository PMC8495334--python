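"""In-silico trypsin digestion with missed-cleavage and terminal-context tracking.

Trypsin cuts C-terminal to K or R; by the Keil rule a following proline
suppresses the cut (on by default, configurable).  Protein N-/C-termini count
as tryptic for downstream "fully tryptic" filters, so a protein C-terminal
peptide that does not end in K/R is still admissible as a marker.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

__all__ = [
    "Protein",
    "Peptide",
    "cleavage_sites",
    "digest",
    "digest_collection",
    "read_fasta",
    "AMBIGUOUS_RESIDUES",
]

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: Residues with undefined mass; peptides containing them are flagged.
AMBIGUOUS_RESIDUES = frozenset("BZXU")


@dataclass(frozen=True)
class Protein:
    identifier: str
    species: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.identifier}: empty sequence")
        bad = set(self.sequence) - STANDARD_RESIDUES - AMBIGUOUS_RESIDUES
        if bad:
            raise ValueError(
                f"protein {self.identifier}: invalid residues {sorted(bad)}"
            )


@dataclass(frozen=True)
class Peptide:
    """A tryptic peptide with provenance into its parent protein.

    ``start``/``end`` are 0-based half-open coordinates in the parent;
    ``missed_cleavages`` counts internal uncut K/R sites; the terminal flags
    record whether each end is a trypsin cut or a protein terminus.
    """

    sequence: str
    protein_id: str
    species: str
    start: int
    end: int
    missed_cleavages: int
    nterm_tryptic: bool
    cterm_tryptic: bool
    has_ambiguous: bool = False

    def __len__(self) -> int:
        return len(self.sequence)


def cleavage_sites(sequence: str, proline_rule: bool = True) -> list[int]:
    """Positions immediately after each K/R cut site, strictly increasing.

    A position ``i`` means trypsin cuts between ``sequence[i-1]`` and
    ``sequence[i]``; a cut after the final residue is included.  With
    ``proline_rule`` a K/R followed by P is not cut.
    """
    sites = []
    for i, res in enumerate(sequence):
        if res in ("K", "R"):
            if proline_rule and i + 1 < len(sequence) and sequence[i + 1] == "P":
                continue
            sites.append(i + 1)
    return sites


def digest(
    protein: Protein,
    max_missed: int = 2,
    min_len: int = 1,
    max_len: int = 100,
    proline_rule: bool = True,
) -> list[Peptide]:
    """Tryptic peptides of ``protein`` with up to ``max_missed`` missed cleavages.

    Output is ordered by start position then length.  At ``max_missed=0`` the
    returned peptides partition the protein sequence (before length filtering).
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    if not 1 <= min_len <= max_len:
        raise ValueError("need 1 <= min_len <= max_len")
    seq = protein.sequence
    cuts = cleavage_sites(seq, proline_rule)
    # Segment boundaries: protein termini plus every cut position.
    bounds = [0] + [c for c in cuts if c < len(seq)] + [len(seq)]
    peptides = []
    n_seg = len(bounds) - 1
    for i in range(n_seg):
        for missed in range(min(max_missed, n_seg - 1 - i) + 1):
            start, end = bounds[i], bounds[i + 1 + missed]
            if not min_len <= end - start <= max_len:
                continue
            sub = seq[start:end]
            peptides.append(
                Peptide(
                    sequence=sub,
                    protein_id=protein.identifier,
                    species=protein.species,
                    start=start,
                    end=end,
                    missed_cleavages=missed,
                    nterm_tryptic=True,  # protein N-terminus or a cut site
                    cterm_tryptic=True,  # protein C-terminus or a cut site
                    has_ambiguous=bool(set(sub) & AMBIGUOUS_RESIDUES),
                )
            )
    peptides.sort(key=lambda p: (p.start, p.end - p.start))
    return peptides


def digest_collection(
    proteins: Iterable[Protein],
    max_missed: int = 2,
    min_len: int = 1,
    max_len: int = 100,
    proline_rule: bool = True,
) -> list[Peptide]:
    """Digest every protein, preserving provenance; empty input gives []."""
    out: list[Peptide] = []
    for protein in proteins:
        out.extend(digest(protein, max_missed, min_len, max_len, proline_rule))
    return out


def read_fasta(path: str | Path, species: str) -> list[Protein]:
    """Read a FASTA file, labelling every record with one species.

    The record identifier is the header up to the first whitespace.
    """
    proteins = [
        Protein(rec.id, species, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not proteins:
        raise ValueError(f"no FASTA records found in {path}")
    return proteins
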