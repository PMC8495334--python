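"""Synthetic fixtures: toy multi-species proteomes and mixture intensity tables.

The proteome generator emulates the five-species screening setting: each
species gets a handful of random proteins assembled from tryptic segments,
with a known set of planted marker peptides (unique to one species after I/L
canonicalisation) and planted shared peptides (present in two or more
species).  Planted peptides are fully tryptic, 9-17 residues, methionine- and
cysteine-free, so they satisfy the default marker filter by construction, and
the generator verifies by digesting its own output that the planted structure
holds — retrying with a fresh draw on collision, bounded.

The intensity simulator emulates the binary-mixture calibration experiment:
intensity = slope x fraction + intercept + Gaussian noise, floored at zero,
with independent replicates.  Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .digest import Protein, digest_collection
from .markers import MarkerFilter, build_index, find_species_specific, peptide_key

__all__ = [
    "ProteomeSpec",
    "IntensitySpec",
    "make_toy_proteomes",
    "write_proteome_fastas",
    "simulate_mixture_intensities",
]

# Background residue alphabet: the 18 standard residues other than K/R, which
# terminate tryptic segments and so control segment lengths.
_NON_CUT_RESIDUES = "ACDEFGHILMNPQSTVWY"
#: Residues allowed in planted markers so they pass the default filter
#: (no K/R interior, no M/C, no I/L to keep canonical keys simple).
_PLANT_ALPHABET = "ADEFGHNPQSTVWY"
# Background tryptic segment lengths deliberately avoid the 9-17 marker
# window so screening recovers exactly the planted peptides; the short/long
# mix keeps overall K/R frequency near the natural ~11%.
_SHORT_SEGMENT = (2, 8)
_LONG_SEGMENT = (18, 30)
_P_SHORT = 0.8


@dataclass(frozen=True)
class ProteomeSpec:
    n_species: int = 5
    n_proteins: int = 20
    protein_length: tuple[int, int] = (80, 200)
    n_unique: int = 3
    n_shared: int = 2
    seed: int = 0
    max_retries: int = 100

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        lo, hi = self.protein_length
        if not 30 <= lo <= hi:
            raise ValueError("protein length range must satisfy 30 <= lo <= hi")


@dataclass(frozen=True)
class IntensitySpec:
    """Linear-response parameters per peptide for mixture simulation."""

    curves: Mapping[str, tuple[float, float]]  # peptide -> (slope, intercept)
    noise_sd: float = 0.0
    fractions: tuple[float, ...] = (0.0, 0.20, 0.40, 0.60, 0.80, 1.00)
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise ValueError("need >= 1 replicate")


def _random_tryptic_peptide(rng: np.random.Generator, lo: int = 9, hi: int = 17) -> str:
    """A fully tryptic marker-grade peptide: clean interior, K/R terminus.

    The first residue is never proline, which would suppress the upstream
    trypsin cut and break the tryptic N-terminus.
    """
    length = int(rng.integers(lo, hi + 1))
    first = str(rng.choice(list(_PLANT_ALPHABET.replace("P", ""))))
    body = "".join(rng.choice(list(_PLANT_ALPHABET), size=length - 2))
    return first + body + str(rng.choice(["K", "R"]))


def _random_background_segment(rng: np.random.Generator) -> str:
    """A tryptic segment whose length avoids the 9-17 marker window."""
    lo, hi = _SHORT_SEGMENT if rng.random() < _P_SHORT else _LONG_SEGMENT
    length = int(rng.integers(lo, hi + 1))
    first = str(rng.choice(list(_NON_CUT_RESIDUES.replace("P", ""))))
    body = "".join(rng.choice(list(_NON_CUT_RESIDUES), size=length - 2))
    return first + body + str(rng.choice(["K", "R"]))


def _random_background_protein(rng: np.random.Generator, length: int) -> list[str]:
    """A protein as a list of tryptic segments totalling at least ``length``."""
    segments, total = [], 0
    while total < length:
        seg = _random_background_segment(rng)
        segments.append(seg)
        total += len(seg)
    return segments


def _assemble(
    rng: np.random.Generator, spec: ProteomeSpec
) -> tuple[dict[str, list[Protein]], pd.DataFrame]:
    species_names = [f"species_{chr(ord('A') + i)}" for i in range(spec.n_species)]
    used_keys: set[str] = set()

    def fresh_peptide() -> str:
        for _ in range(spec.max_retries):
            pep = _random_tryptic_peptide(rng)
            if peptide_key(pep) not in used_keys:
                used_keys.add(peptide_key(pep))
                return pep
        raise RuntimeError("could not draw a fresh planted peptide")

    unique = {sp: [fresh_peptide() for _ in range(spec.n_unique)] for sp in species_names}
    shared = [fresh_peptide() for _ in range(spec.n_shared)]

    proteomes: dict[str, list[Protein]] = {}
    truth_rows = []
    for sp in species_names:
        lo, hi = spec.protein_length
        segmented = [
            _random_background_protein(rng, int(rng.integers(lo, hi + 1)))
            for _ in range(spec.n_proteins)
        ]
        # Plant each peptide at a segment boundary of one random protein: the
        # preceding segment's K/R terminus makes its N-terminus tryptic.
        for pep in unique[sp] + shared:
            host = int(rng.integers(0, spec.n_proteins))
            slot = int(rng.integers(0, len(segmented[host]) + 1))
            segmented[host].insert(slot, pep)
        proteomes[sp] = [
            Protein(f"{sp}_prot{j:03d}", sp, "".join(segs))
            for j, segs in enumerate(segmented)
        ]
        for pep in unique[sp]:
            truth_rows.append({"species": sp, "sequence": pep, "role": "unique"})
    for pep in shared:
        truth_rows.append({"species": "*", "sequence": pep, "role": "shared"})
    truth = pd.DataFrame(truth_rows, columns=["species", "sequence", "role"])
    return proteomes, truth


def _structure_holds(
    proteomes: dict[str, list[Protein]], truth: pd.DataFrame
) -> bool:
    """Verify by digestion + screening that the planted structure is exact."""
    peptides = digest_collection(
        [p for prots in proteomes.values() for p in prots], max_missed=0
    )
    index = build_index(peptides, equate_il=True)
    filt = MarkerFilter()
    for sp in proteomes:
        planted = set(truth.loc[truth.species == sp, "sequence"])
        found = {m.sequence for m in find_species_specific(index, sp, filt)}
        if found != planted:
            return False
    shared = truth.loc[truth.role == "shared", "sequence"]
    for pep in shared:
        if len(index.species_of(peptide_key(pep))) < 2:
            return False
    return True


def make_toy_proteomes(
    spec: ProteomeSpec = ProteomeSpec(),
) -> tuple[dict[str, list[Protein]], pd.DataFrame]:
    """Generate per-species proteomes with known marker ground truth.

    Returns (species -> proteins, truth table with columns species/sequence/
    role).  Unique planted peptides are recoverable as exactly the marker set
    of their species under the default filter; shared ones appear in every
    species.  Regenerates on collision up to ``spec.max_retries`` times.
    """
    rng = np.random.default_rng(spec.seed)
    for _ in range(spec.max_retries):
        proteomes, truth = _assemble(rng, spec)
        if _structure_holds(proteomes, truth):
            return proteomes, truth
    raise RuntimeError(
        "planted marker structure kept colliding with background; "
        "try a different seed or smaller proteomes"
    )


def write_proteome_fastas(
    proteomes: Mapping[str, list[Protein]], outdir: str | Path
) -> dict[str, Path]:
    """One FASTA per species; byte-deterministic for a given proteome set."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for sp in sorted(proteomes):
        path = outdir / f"{sp}.fasta"
        with open(path, "w") as fh:
            for prot in proteomes[sp]:
                fh.write(f">{prot.identifier}\n")
                for i in range(0, len(prot.sequence), 60):
                    fh.write(prot.sequence[i : i + 60] + "\n")
        paths[sp] = path
    return paths


def simulate_mixture_intensities(spec: IntensitySpec) -> pd.DataFrame:
    """Simulate a calibration intensity table.

    One row per (level, replicate): columns ``sample_id``, ``fraction``,
    ``replicate``, then one intensity column per peptide.  Gaussian noise with
    ``noise_sd`` is added independently per cell and the result floored at 0.
    """
    rng = np.random.default_rng(spec.seed)
    peptides = list(spec.curves)
    rows = []
    for level, fraction in enumerate(spec.fractions):
        for rep in range(spec.replicates):
            row = {
                "sample_id": f"L{level}R{rep}",
                "fraction": fraction,
                "replicate": rep,
            }
            for pep in peptides:
                slope, intercept = spec.curves[pep]
                value = slope * fraction + intercept
                if spec.noise_sd > 0:
                    value += rng.normal(0.0, spec.noise_sd)
                row[pep] = max(0.0, value)
            rows.append(row)
    return pd.DataFrame(rows)
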