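"""MRM transition design: precursor/product m/z, collision energy, export.

A transition pairs a doubly protonated tryptic precursor with one singly
charged y-ion product.  Collision energy follows the standard triple-quadrupole
charge-dependent linear ramp, CE = slope x (m/z / 100) + offset; the default
2+ ramp is 3.1 V per 100 m/z with a +1.0 V offset.  Which y-ion responds best
cannot be predicted from sequence alone, so the default selection mode takes
the empirically observed product per peptide; 'rank' mode emits the high-m/z
y-ion candidates as a starting panel for instrument optimisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .digest import Peptide
from .masses import (
    CARBAMIDOMETHYL,
    DEFAULT_TABLE,
    ModifiedPeptide,
    ResidueMassTable,
    apply_fixed_modifications,
    fragment_mz,
    precursor_mz,
)

__all__ = [
    "CEModel",
    "Transition",
    "collision_energy",
    "candidate_products",
    "build_transitions",
    "export_transition_list",
    "read_transition_list",
    "DEFAULT_CE_MODEL",
]


@dataclass(frozen=True)
class CEModel:
    """Per-charge linear collision-energy ramp: slope in V per 100 m/z, offset in V."""

    ramps: Mapping[int, tuple[float, float]] = field(
        default_factory=lambda: {2: (3.1, 1.0)}
    )

    def parameters(self, charge: int) -> tuple[float, float]:
        try:
            return self.ramps[charge]
        except KeyError:
            raise KeyError(
                f"no collision-energy ramp configured for charge {charge}+"
            ) from None


DEFAULT_CE_MODEL = CEModel()


def collision_energy(
    precursor: float, charge: int, model: CEModel = DEFAULT_CE_MODEL
) -> float:
    """Ramp CE for a precursor m/z, rounded to one decimal (instrument input)."""
    if precursor <= 0:
        raise ValueError("precursor m/z must be positive")
    slope, offset = model.parameters(charge)
    return round(slope * precursor / 100.0 + offset, 1)


@dataclass(frozen=True)
class Transition:
    species: str
    sequence: str
    precursor_mz: float
    precursor_charge: int
    product_ion: str  # e.g. "y7"
    product_mz: float
    product_charge: int
    collision_energy: float
    retention_time: float | None = None  # empirical metadata, never predicted


def candidate_products(
    p: ModifiedPeptide,
    precursor_charge: int = 2,
    min_index: int = 3,
    mz_range: tuple[float, float] = (300.0, 1400.0),
    include_b: bool = False,
    table: ResidueMassTable = DEFAULT_TABLE,
) -> list[tuple[str, float]]:
    """Singly charged y-ion candidates, high m/z first (ties by index ascending).

    Low-index ions are excluded (poor selectivity); candidates outside the
    instrument's product m/z window are dropped.  b-ions, if requested, are
    appended after all y-ions.
    """
    lo, hi = mz_range
    out: list[tuple[str, float]] = []
    for series in ("y",) + (("b",) if include_b else ()):
        ions = []
        for index in range(min_index, len(p.sequence)):
            mz = fragment_mz(p, series, index, charge=1, table=table)
            if lo <= mz <= hi:
                ions.append((f"{series}{index}", mz, index))
        ions.sort(key=lambda t: (-t[1], t[2]))
        out.extend((label, mz) for label, mz, _ in ions)
    return out


def _as_modified(sequence: str) -> ModifiedPeptide:
    return apply_fixed_modifications(sequence, (CARBAMIDOMETHYL,))


def build_transitions(
    markers: Sequence[Peptide | str],
    ce_model: CEModel = DEFAULT_CE_MODEL,
    selection: str = "empirical",
    empirical: Mapping[str, str] | None = None,
    k: int = 3,
    precursor_charge: int = 2,
    min_index: int = 3,
    mz_range: tuple[float, float] = (300.0, 1400.0),
    retention_times: Mapping[str, float] | None = None,
    species_of: Mapping[str, str] | None = None,
    table: ResidueMassTable = DEFAULT_TABLE,
) -> list[Transition]:
    """Build transitions for marker peptides.

    ``selection='empirical'`` requires ``empirical``, a map sequence -> product
    ion label (e.g. "y7") naming the observed best responder; ``'rank'`` emits
    the top ``k`` candidates from :func:`candidate_products` per marker.
    Markers may be Peptide records (species from provenance) or bare sequences
    (species from ``species_of``, default "unknown").
    """
    if selection not in ("empirical", "rank"):
        raise ValueError(f"selection must be 'empirical' or 'rank', got {selection!r}")
    if selection == "empirical" and empirical is None:
        raise ValueError("empirical selection requires a sequence -> product ion map")
    transitions = []
    for marker in markers:
        seq = marker if isinstance(marker, str) else marker.sequence
        species = (
            (species_of or {}).get(seq, "unknown")
            if isinstance(marker, str)
            else marker.species
        )
        modified = _as_modified(seq)
        prec = precursor_mz(modified, precursor_charge, table)
        ce = collision_energy(prec, precursor_charge, ce_model)
        rt = (retention_times or {}).get(seq)
        if selection == "empirical":
            label = empirical[seq]
            index = int(label[1:])
            mz = fragment_mz(modified, label[0], index, charge=1, table=table)
            chosen = [(label, mz)]
        else:
            chosen = candidate_products(
                modified, precursor_charge, min_index, mz_range, table=table
            )[:k]
        for label, mz in chosen:
            transitions.append(
                Transition(
                    species=species,
                    sequence=seq,
                    precursor_mz=prec,
                    precursor_charge=precursor_charge,
                    product_ion=label,
                    product_mz=mz,
                    product_charge=1,
                    collision_energy=ce,
                    retention_time=rt,
                )
            )
    return transitions


_EXPORT_COLUMNS = [
    "compound_name", "precursor_mz", "product_mz", "precursor_charge",
    "product_ion", "product_charge", "collision_energy", "retention_time",
    "species",
]


def export_transition_list(
    transitions: Iterable[Transition], path: str | Path
) -> None:
    """Write a vendor-neutral transition list CSV.

    m/z to 6 decimals, CE to 1, RT to 3 (blank when absent); stable row order
    as given.
    """
    rows = []
    for t in transitions:
        rows.append(
            {
                "compound_name": t.sequence,
                "precursor_mz": f"{t.precursor_mz:.6f}",
                "product_mz": f"{t.product_mz:.6f}",
                "precursor_charge": t.precursor_charge,
                "product_ion": t.product_ion,
                "product_charge": t.product_charge,
                "collision_energy": f"{t.collision_energy:.1f}",
                "retention_time": (
                    "" if t.retention_time is None else f"{t.retention_time:.3f}"
                ),
                "species": t.species,
            }
        )
    pd.DataFrame(rows, columns=_EXPORT_COLUMNS).to_csv(path, index=False)


def read_transition_list(path: str | Path) -> list[Transition]:
    """Read a CSV written by :func:`export_transition_list`."""
    df = pd.read_csv(path, dtype={"compound_name": str})
    out = []
    for row in df.itertuples(index=False):
        rt = getattr(row, "retention_time")
        out.append(
            Transition(
                species=str(row.species),
                sequence=str(row.compound_name),
                precursor_mz=float(row.precursor_mz),
                precursor_charge=int(row.precursor_charge),
                product_ion=str(row.product_ion),
                product_mz=float(row.product_mz),
                product_charge=int(row.product_charge),
                collision_energy=float(row.collision_energy),
                retention_time=None if pd.isna(rt) else float(rt),
            )
        )
    return out
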