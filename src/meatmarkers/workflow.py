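"""Run configuration and end-to-end pipeline stages.

The YAML run configuration names the per-species FASTA inputs, digestion
parameters, marker filter, transition parameters and quantification inputs.
Each stage validates its inputs before computing, logs what it did, and writes
plain CSV outputs that the next stage (or any targeted-proteomics tool) can
read.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from .digest import digest_collection, read_fasta
from .markers import (
    MarkerFilter,
    build_index,
    find_species_specific,
    write_marker_table,
)
from .quantify import (
    MixtureDesign,
    MixtureSample,
    detect_contaminant,
    detection_threshold,
    fit_standard_curve,
)
from .transitions import (
    CEModel,
    build_transitions,
    export_transition_list,
)

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "run_screen",
    "run_design",
    "run_quantify",
]

log = logging.getLogger("meatmarkers")


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    species_fasta: dict[str, Path]
    output_dir: Path
    max_missed: int = 2
    min_len: int = 1
    max_len: int = 100
    proline_rule: bool = True
    marker_filter: MarkerFilter = field(default_factory=MarkerFilter)
    equate_il: bool = True
    precursor_charge: int = 2
    min_product_index: int = 3
    product_mz_range: tuple[float, float] = (300.0, 1400.0)
    selection: str = "empirical"
    k: int = 3
    ce_model: CEModel = field(default_factory=CEModel)
    quantify_target: str | None = None
    quantify_background: str | None = None
    calibration_path: Path | None = None
    unknowns_path: Path | None = None
    panel_path: Path | None = None
    seed: int = 0
    log_level: str = "INFO"

    def digest_params(self) -> dict[str, Any]:
        return dict(
            max_missed=self.max_missed,
            min_len=self.min_len,
            max_len=self.max_len,
            proline_rule=self.proline_rule,
        )


def _config_hash(raw: Mapping[str, Any]) -> str:
    return hashlib.sha256(
        yaml.safe_dump(raw, sort_keys=True).encode()
    ).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Referenced input paths must exist; failures raise :class:`ConfigError`
    before any stage runs.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    base = path.parent

    def respath(value: str) -> Path:
        p = Path(value)
        return p if p.is_absolute() else base / p

    species_fasta = {
        str(sp): respath(str(fp))
        for sp, fp in (raw.get("species_fasta") or {}).items()
    }
    for sp, fp in species_fasta.items():
        if not fp.exists():
            raise ConfigError(f"FASTA for species {sp!r} not found: {fp}")

    dig = raw.get("digestion") or {}
    mf = raw.get("marker_filter") or {}
    try:
        marker_filter = MarkerFilter(
            min_len=int(mf.get("min_len", 9)),
            max_len=int(mf.get("max_len", 17)),
            max_missed_for_marker=int(mf.get("max_missed", 0)),
            require_tryptic_termini=bool(mf.get("require_tryptic_termini", True)),
            exclude_residues=frozenset(mf.get("exclude_residues", ["M"])),
        )
    except ValueError as exc:
        raise ConfigError(f"invalid marker_filter: {exc}") from exc

    tr = raw.get("transitions") or {}
    ramps = {
        int(charge): (float(slope), float(offset))
        for charge, (slope, offset) in (tr.get("ce_model") or {2: (3.1, 1.0)}).items()
    }
    selection = str(tr.get("selection", "empirical"))
    if selection not in ("empirical", "rank"):
        raise ConfigError(f"transitions.selection must be empirical|rank: {selection}")

    qt = raw.get("quantify") or {}

    def optpath(key: str) -> Path | None:
        value = qt.get(key)
        if value is None:
            return None
        p = respath(str(value))
        if not p.exists():
            raise ConfigError(f"quantify.{key} not found: {p}")
        return p

    config = RunConfig(
        species_fasta=species_fasta,
        output_dir=respath(str(raw.get("output_dir", "out"))),
        max_missed=int(dig.get("max_missed", 2)),
        min_len=int(dig.get("min_len", 1)),
        max_len=int(dig.get("max_len", 100)),
        proline_rule=bool(dig.get("proline_rule", True)),
        marker_filter=marker_filter,
        equate_il=bool(mf.get("equate_il", True)),
        precursor_charge=int(tr.get("precursor_charge", 2)),
        min_product_index=int(tr.get("min_product_index", 3)),
        product_mz_range=tuple(tr.get("product_mz_range", (300.0, 1400.0))),
        selection=selection,
        k=int(tr.get("k", 3)),
        ce_model=CEModel(ramps),
        quantify_target=qt.get("target"),
        quantify_background=qt.get("background"),
        calibration_path=optpath("calibration"),
        unknowns_path=optpath("unknowns"),
        panel_path=optpath("panel"),
        seed=int(raw.get("seed", 0)),
        log_level=str(raw.get("log_level", "INFO")),
    )
    log.info("loaded config %s (hash %s)", path, _config_hash(raw))
    return config


def run_screen(config: RunConfig) -> Path:
    """Digest every configured proteome, index, and screen species markers.

    Writes ``markers.csv`` in the output directory and returns its path.
    """
    if len(config.species_fasta) < 2:
        raise ConfigError("marker screening needs FASTA inputs for >= 2 species")
    proteins_by_species = {
        sp: read_fasta(fp, sp) for sp, fp in sorted(config.species_fasta.items())
    }
    peptides = digest_collection(
        [p for prots in proteins_by_species.values() for p in prots],
        **config.digest_params(),
    )
    index = build_index(peptides, equate_il=config.equate_il)
    markers = []
    for sp in sorted(proteins_by_species):
        found = find_species_specific(index, sp, config.marker_filter)
        log.info("species %s: %d specific marker peptides", sp, len(found))
        markers.extend(found)
    config.output_dir.mkdir(parents=True, exist_ok=True)
    out = config.output_dir / "markers.csv"
    write_marker_table(markers, out)
    return out


def run_design(
    config: RunConfig,
    markers_path: str | Path,
    empirical_path: str | Path | None = None,
) -> Path:
    """Build and export the transition list for a marker table.

    ``empirical_path`` is a CSV with columns ``sequence, product_ion`` and
    optionally ``retention_time``; required in 'empirical' selection mode.
    Writes ``transitions.csv`` and returns its path.
    """
    markers_df = pd.read_csv(markers_path)
    empirical = retention = None
    if empirical_path is not None:
        emp = pd.read_csv(empirical_path)
        empirical = dict(zip(emp["sequence"], emp["product_ion"]))
        if "retention_time" in emp.columns:
            retention = {
                s: float(rt)
                for s, rt in zip(emp["sequence"], emp["retention_time"])
                if pd.notna(rt)
            }
    if config.selection == "empirical" and empirical is None:
        raise ConfigError("empirical selection mode requires an empirical table")
    species_of = dict(zip(markers_df["sequence"], markers_df["species"]))
    transitions = build_transitions(
        list(markers_df["sequence"]),
        ce_model=config.ce_model,
        selection=config.selection,
        empirical=empirical,
        k=config.k,
        precursor_charge=config.precursor_charge,
        min_index=config.min_product_index,
        mz_range=config.product_mz_range,
        retention_times=retention,
        species_of=species_of,
    )
    if not transitions:
        log.warning("no markers given; writing header-only transition list")
    config.output_dir.mkdir(parents=True, exist_ok=True)
    out = config.output_dir / "transitions.csv"
    export_transition_list(transitions, out)
    return out


def _fit_curves(
    calibration: pd.DataFrame, peptides: list[str], design: MixtureDesign
) -> dict[str, Any]:
    curves = {}
    for pep in peptides:
        if pep not in calibration.columns:
            continue
        replicate_sets = [
            list(calibration.loc[calibration["fraction"] == f, pep])
            for f in design.fractions
        ]
        curves[pep] = fit_standard_curve(design, replicate_sets, pep)
    return curves


def run_quantify(config: RunConfig) -> tuple[Path, Path]:
    """Fit standard curves, quantify unknown samples, and write the report.

    Requires ``quantify.panel`` (CSV: species, sequence), ``calibration``
    (CSV: sample_id, fraction, one intensity column per peptide; fraction is
    the mass fraction of ``quantify.target``) and ``unknowns`` (CSV:
    sample_id plus intensity columns).  Writes ``report.csv`` and
    ``report.txt`` and returns both paths.
    """
    if config.panel_path is None or config.unknowns_path is None:
        raise ConfigError("quantify needs panel and unknowns paths")
    panel_df = pd.read_csv(config.panel_path)
    panel = {
        sp: sorted(group["sequence"])
        for sp, group in panel_df.groupby("species")
    }

    curves: dict[str, Any] = {}
    thresholds: dict[str, float] = {}
    if config.calibration_path is not None:
        if config.quantify_target is None or config.quantify_background is None:
            raise ConfigError("calibration requires quantify.target and .background")
        calibration = pd.read_csv(config.calibration_path)
        fractions = tuple(sorted(set(calibration["fraction"])))
        design = MixtureDesign(
            config.quantify_target, config.quantify_background, fractions
        )
        target_peps = panel.get(config.quantify_target, [])
        curves = _fit_curves(calibration, target_peps, design)
        blanks = calibration[calibration["fraction"] == 0.0]
        for pep in calibration.columns:
            if pep in {"sample_id", "fraction", "replicate"}:
                continue
            if len(blanks) >= 2:
                thresholds[pep] = detection_threshold(list(blanks[pep]))
        missing = [p for p in target_peps if p not in curves]
        if missing:
            log.warning("no calibration columns for: %s", ", ".join(missing))

    unknowns = pd.read_csv(config.unknowns_path)
    rows = []
    lines = []
    for row in unknowns.itertuples(index=False):
        intensities = {
            col: float(getattr(row, col))
            for col in unknowns.columns
            if col != "sample_id"
        }
        sample = MixtureSample(str(row.sample_id), intensities)
        for call in detect_contaminant(sample, panel, curves, thresholds):
            rows.append(
                {
                    "sample_id": sample.sample_id,
                    "species": call.species,
                    "detected": call.detected,
                    "fraction": call.fraction,
                    "spread": call.spread,
                    "supporting_peptides": ";".join(call.supporting_peptides),
                }
            )
            if call.detected:
                frac = (
                    "fraction n/a"
                    if call.fraction is None
                    else f"fraction {call.fraction:.3f} (MAD {call.spread:.3f})"
                )
                lines.append(
                    f"{sample.sample_id}: {call.species} DETECTED via "
                    f"{', '.join(call.supporting_peptides)}; {frac}"
                )
                if call.fraction is None:
                    log.warning(
                        "%s: %s detected but no standard curve available",
                        sample.sample_id,
                        call.species,
                    )
    config.output_dir.mkdir(parents=True, exist_ok=True)
    report_csv = config.output_dir / "report.csv"
    report_txt = config.output_dir / "report.txt"
    pd.DataFrame(
        rows,
        columns=[
            "sample_id", "species", "detected", "fraction", "spread",
            "supporting_peptides",
        ],
    ).to_csv(report_csv, index=False)
    report_txt.write_text(
        "\n".join(lines) + "\n" if lines else "no species detected\n"
    )
    return report_csv, report_txt
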