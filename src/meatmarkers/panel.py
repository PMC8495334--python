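"""The published 15-peptide MRM panel for beef/chicken/duck/pork/lamb speciation.

Each entry carries the species, the marker sequence, the instrument-optimised
(empirical) quantities — chosen product ion and retention time in minutes —
and the published doubly protonated precursor m/z, singly charged product m/z
and collision energy in volts.  The published numbers are assay inputs and
cross-check anchors; the package recomputes masses and CE from sequence.

The FLEELLTTQC entry is flagged ``mass_consistent=False``: its published
precursor m/z cannot be reconciled with the printed sequence under any
standard cysteine modification (computed 2+ carbamidomethyl m/z ~ 627.31 vs
published 762.87), pointing to a truncated or mistyped sequence in the source
table.  Its CE is still consistent with the published precursor under the
default ramp, so it participates in CE checks only.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["PanelEntry", "REFERENCE_PANEL", "mass_consistent_panel"]


@dataclass(frozen=True)
class PanelEntry:
    species: str
    sequence: str
    published_precursor_mz: float  # 2+
    published_product_mz: float  # 1+
    product_ion: str  # empirical best responder, y-series
    retention_time: float  # min, empirical
    published_ce: float  # V
    mass_consistent: bool = True


REFERENCE_PANEL: tuple[PanelEntry, ...] = (
    PanelEntry("beef", "TLEDQVNELK", 594.808967, 845.436323, "y7", 7.142, 19.4),
    PanelEntry("beef", "GLSDSVSIGPVTVK", 679.879924, 899.556044, "y9", 9.465, 22.1),
    PanelEntry(
        "beef", "FLEELLTTQC", 762.871773, 1006.49861, "y8", 10.549, 24.6,
        mass_consistent=False,
    ),
    PanelEntry("chicken", "LVSWYDNEFGYSNR", 875.397001, 1264.52291, "y10", 14.072, 28.1),
    PanelEntry("chicken", "IGDEFVADLDQLQR", 809.907201, 1057.56365, "y9", 12.472, 26.1),
    PanelEntry("chicken", "LDVPISGEPAPTVTWK", 855.45907, 1382.73144, "y13", 11.566, 27.5),
    PanelEntry("chicken", "ECQTLVSDVDYR", 742.83793, 966.489087, "y8", 9.529, 24.0),
    PanelEntry("duck", "VVFDDSFDR", 550.256371, 901.368637, "y7", 8.38, 18.1),
    PanelEntry("duck", "IVESLQSSLDAEIR", 780.417402, 1018.51636, "y9", 9.645, 25.2),
    PanelEntry("duck", "LAILENANVLAR", 648.885344, 999.558169, "y9", 10.535, 21.1),
    PanelEntry("pork", "VNVDEVGGEALGR", 657.836048, 887.458121, "y9", 7.124, 21.4),
    PanelEntry("pork", "DQGSYEDFVEGLR", 757.841527, 1127.53677, "y9", 10.346, 24.5),
    PanelEntry("lamb", "SPPNPENIAPGYSGPLK", 869.443951, 1342.70014, "y13", 7.954, 28.0),
    PanelEntry("lamb", "HVLTTLGER", 513.290548, 789.446494, "y7", 5.044, 16.9),
    PanelEntry("lamb", "NLVHIITHGEEKD", 752.891354, 1041.52112, "y9", 6.188, 24.3),
)


def mass_consistent_panel() -> tuple[PanelEntry, ...]:
    """The 14 entries whose masses are reproducible from their sequences."""
    return tuple(e for e in REFERENCE_PANEL if e.mass_consistent)
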