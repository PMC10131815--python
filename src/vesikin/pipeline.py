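"""Configuration loading and the end-to-end quantification pipeline.

The pipeline composes the analysis chain: sequence -> molecular weight ->
standard-curve quantification -> copy numbers -> per-unit stoichiometry ->
peaks and contrasts.  Every constant used (molecular weights, Avogadro,
thresholds) is echoed into the report for auditability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import vegfa
from .kinetics import TimeCourse, PeakResult, compartment_contrast, find_peak
from .qpcr_quant import (
    QcError,
    StandardCurve,
    StandardPoint,
    amplification_efficiency,
    build_standard_curve,
    interpolate_quantity,
    quantity_to_copies,
)
from .seqchem import (
    composition,
    parse_fasta,
    protein_molecular_weight,
    rna_molecular_weight,
    translate,
)
from .stoichiometry import AVOGADRO, per_unit_copies

__all__ = ["PipelineConfig", "PipelineResult", "load_config", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (YAML dialect)."""

    standards_csv: str
    unknowns_csv: str
    sequence_fasta: str | None = None
    mw_g_per_mol: float = vegfa.FULL_LENGTH_MW
    protein_mw_g_per_mol: float = vegfa.PROTEIN_MW_KDA * 1000.0
    r2_threshold: float = 0.975
    adjust: str = "holm"
    out_dir: str = "results"
    seed: int = 0
    force: bool = False

    # keys the user set explicitly (the rest carry package defaults)
    provided_keys: frozenset[str] = field(default_factory=frozenset, compare=False)


_REQUIRED_KEYS = ("standards_csv", "unknowns_csv")


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping of keys to values")
    known = {f.name for f in fields(PipelineConfig)} - {"provided_keys"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}; allowed: {sorted(known)}")
    missing = [k for k in _REQUIRED_KEYS if k not in raw]
    if missing:
        raise ValueError(f"missing required config keys: {missing}")
    cfg = PipelineConfig(**raw, provided_keys=frozenset(raw))
    base = Path(path).parent
    for key in ("standards_csv", "unknowns_csv", "sequence_fasta"):
        value = getattr(cfg, key)
        if value is None:
            continue
        resolved = Path(value) if Path(value).is_absolute() else base / value
        if not resolved.exists():
            raise FileNotFoundError(f"config key {key}: file not found: {resolved}")
        setattr(cfg, key, str(resolved))
    return cfg


@dataclass
class PipelineResult:
    curve: StandardCurve
    results: pd.DataFrame
    peaks: dict[str, PeakResult]
    contrasts: dict[str, float]
    report: str


def _sequence_section(cfg: PipelineConfig, lines: list[str]) -> None:
    seqs = parse_fasta(Path(cfg.sequence_fasta).read_text(), alphabet="rna")
    for seq in seqs:
        comp = composition(seq)
        mw = rna_molecular_weight(seq, triphosphate=True)
        lines.append(f"- sequence `{seq.name}`: {len(seq)} nt; counts {comp.counts}")
        lines.append(f"  - RNA MW (with 5' triphosphate): {mw:.1f} g/mol")
        if len(seq) % 3 == 0 and seq.residues.startswith("AUG"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                prot = translate(seq)
            lines.append(
                f"  - translates to {len(prot)} aa; protein MW "
                f"{protein_molecular_weight(prot) / 1000.0:.5f} kDa"
            )


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the full quantification chain and write results + report.

    Raises :class:`~vesikin.qpcr_quant.QcError` if the standard curve fails
    its R^2 gate and ``force`` is not set.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines = ["# Quantification report", ""]
    lines.append("## Constants")
    lines.append(f"- Avogadro: {AVOGADRO:.8e} /mol")
    lines.append(f"- mRNA MW: {cfg.mw_g_per_mol} g/mol")
    lines.append(f"- protein MW: {cfg.protein_mw_g_per_mol} g/mol")
    lines.append(f"- R^2 threshold: {cfg.r2_threshold}")
    defaulted = sorted(
        {f.name for f in fields(PipelineConfig)} - set(cfg.provided_keys) - {"provided_keys"}
    )
    lines.append(f"- config keys at package defaults: {defaulted}")
    lines.append("")

    if cfg.sequence_fasta:
        lines.append("## Sequences")
        _sequence_section(cfg, lines)
        lines.append("")

    standards = pd.read_csv(cfg.standards_csv)
    points = [
        StandardPoint(quantity_ng=row.quantity_ng, cq=row.cq)
        for row in standards.itertuples()
    ]
    curve = build_standard_curve(points, r2_threshold=cfg.r2_threshold)
    lines.append("## Standard curve")
    lines.append(
        f"- slope {curve.slope:.4f} Cq/decade, intercept {curve.intercept:.4f} Cq, "
        f"R^2 {curve.r_squared:.5f}, efficiency {amplification_efficiency(curve.slope):.1f}%"
    )
    lines.append(f"- QC (R^2 > {cfg.r2_threshold}): {'PASS' if curve.qc_pass else 'FAIL'}")
    if not curve.qc_pass and not cfg.force:
        raise QcError(
            f"standard curve failed QC: R^2 = {curve.r_squared:.4f} <= {cfg.r2_threshold}"
        )
    lines.append("")

    unknowns = pd.read_csv(cfg.unknowns_csv)
    if "sample_id" not in unknowns.columns or "cq" not in unknowns.columns:
        raise ValueError("unknowns CSV must have sample_id and cq columns")
    rows = []
    for sample_id, group in unknowns.groupby("sample_id", sort=False):
        cq = float(group["cq"].mean())
        quantity = interpolate_quantity(curve, cq, allow_qc_fail=cfg.force)
        ng = quantity.quantity_ng
        if "dilution_factor" in group.columns and group["dilution_factor"].notna().any():
            ng *= float(group["dilution_factor"].iloc[0])
        copies = quantity_to_copies(ng, cfg.mw_g_per_mol).copies
        row = {
            "sample_id": sample_id,
            "mean_cq": cq,
            "quantity_ng": ng,
            "extrapolated": quantity.extrapolated,
            "copies": copies,
        }
        for unit_col, label in (("cells", "copies_per_cell"), ("ev_count", "copies_per_ev")):
            if unit_col in group.columns and group[unit_col].notna().any():
                row[label] = per_unit_copies(copies, float(group[unit_col].iloc[0])).value
        for meta in ("timepoint_h", "compartment"):
            if meta in group.columns and group[meta].notna().any():
                row[meta] = group[meta].iloc[0]
        rows.append(row)
    results = pd.DataFrame(rows)

    peaks: dict[str, PeakResult] = {}
    contrasts: dict[str, float] = {}
    if {"timepoint_h", "compartment"} <= set(results.columns):
        per_unit_col = results.get("copies_per_cell")
        tc_rows = []
        for _, row in results.iterrows():
            if pd.isna(row.get("compartment")) or pd.isna(row.get("timepoint_h")):
                continue
            value = row.get("copies_per_cell")
            if pd.isna(value):
                value = row.get("copies_per_ev")
            if pd.isna(value):
                value = row["copies"]
            tc_rows.append(
                (float(row["timepoint_h"]), row["compartment"], row["sample_id"], float(value), "copies")
            )
        if tc_rows:
            tc = TimeCourse.from_records(tc_rows)
            lines.append("## Kinetics")
            for compartment in sorted(set(tc.records["compartment"])):
                timepoint_count = tc.records[tc.records["compartment"] == compartment][
                    "timepoint_h"
                ].nunique()
                if timepoint_count >= 2:
                    peak = find_peak(tc, compartment)
                    peaks[compartment] = peak
                    lines.append(
                        f"- {compartment} peak: {peak.mean_value:.1f} copies at "
                        f"{peak.timepoint_h:g} h{' (tied)' if peak.tied else ''}"
                    )
            if "cell" in peaks and "EV" in set(tc.records["compartment"]):
                t_peak = peaks["cell"].timepoint_h
                try:
                    fold = compartment_contrast(tc, "cell", "EV", t_peak)
                except ValueError:
                    fold = None
                if fold is not None:
                    contrasts[f"cell_vs_EV_at_{t_peak:g}h"] = fold
                    lines.append(f"- cell vs EV at {t_peak:g} h: {fold:.1f}-fold")
            lines.append("")

    results_path = out_dir / "results.csv"
    results.to_csv(results_path, index=False)
    lines.append(f"Results table: {results_path}")
    report = "\n".join(lines) + "\n"
    (out_dir / "report.md").write_text(report)
    return PipelineResult(
        curve=curve, results=results, peaks=peaks, contrasts=contrasts, report=report
    )
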