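"""End-to-end driver: affinity tables to energy logos, boundaries and overlaps.

``analyze_binding_table`` runs the single-variant chain — relative binding
energies, single-mutant energy matrix, Boltzmann frequencies, Ri model,
scores over the full site library, and the specific/non-specific boundary.
``run_pipeline`` composes the chain over a multi-variant input (a TSV bundle
or workbook, optional peak tables), writes the per-variant reports, the
pairwise KLD table and the cross-variant overlap summaries under one output
directory, and records a manifest with input hashes and every convention
switch used.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import io as tfio
from .boundary import BoundaryEstimate, boundary_report, estimate_boundary
from .chromatogram import selection_logo
from .compare import pairwise_kld
from .constants import DEFAULT_TEMPERATURE_K
from .energetics import BindingTable, energy_matrix_from_single_mutants, relative_binding_energies
from .matrices import (
    EnergyMatrix,
    FrequencyMatrix,
    RiModel,
    boltzmann_frequencies,
    information_content,
    ri_weights,
    score_sites,
)
from .overlap import overlap_quadrants

logger = logging.getLogger("tfspec")

__all__ = ["VariantAnalysis", "PipelineConfig", "analyze_binding_table", "run_pipeline"]


@dataclass(frozen=True)
class VariantAnalysis:
    """Everything the single-variant chain derives from one binding table."""

    variant_id: str
    ddg: pd.Series
    energy_matrix: EnergyMatrix
    frequencies: FrequencyMatrix
    ri_model: RiModel
    scores: pd.Series
    boundary: BoundaryEstimate
    information_bits: float


def analyze_binding_table(
    bt: BindingTable,
    consensus: str | None = None,
    positions: list[int] | None = None,
    ri_pseudocount: float = 0.0,
    threshold: float = 0.0,
    boundary_method: str = "intersection",
) -> VariantAnalysis:
    """Single-variant chain from measured Ka to a boundary estimate.

    The consensus defaults to the variant's strongest site; position labels
    default to the -(L-1)..0 frame of the varied core. Energy-derived
    frequencies use pseudocount 0 (Boltzmann probabilities are never zero)
    and no small-sample correction (no site count stands behind them).
    """
    if consensus is None:
        consensus = bt.strongest_site
    length = len(consensus)
    if positions is None:
        positions = list(range(-(length - 1), 1))
    ddg = relative_binding_energies(bt)
    em = energy_matrix_from_single_mutants(
        ddg, consensus, positions=positions, temperature_K=bt.temperature_K
    )
    fm = boltzmann_frequencies(em)
    rm = ri_weights(fm, pseudocount=ri_pseudocount, apply_correction=False)
    scores = score_sites(rm, list(ddg.index))
    boundary = estimate_boundary(scores, ddg, threshold=threshold, method=boundary_method)
    info = information_content(fm, apply_correction=False)
    return VariantAnalysis(
        variant_id=bt.variant_id,
        ddg=ddg,
        energy_matrix=em,
        frequencies=fm,
        ri_model=rm,
        scores=scores,
        boundary=boundary,
        information_bits=info.total,
    )


@dataclass
class PipelineConfig:
    """Inputs, convention switches and output location for one pipeline run."""

    binding_input: str | None = None  # TSV bundle dir or .xlsx workbook
    peak_tables: Mapping[str, str] = field(default_factory=dict)  # variant -> TSV
    output_dir: str = "tfspec_out"
    temperature_K: float = DEFAULT_TEMPERATURE_K
    count_pseudocount: float | None = None  # None = 0.5/|alphabet|
    ri_pseudocount: float = 0.0
    kld_pseudocount: float = 1e-6
    kld_symmetrize: bool = True
    kld_aggregate: str = "mean"
    kld_log_base: float = 2.0
    boundary_method: str = "intersection"
    ri_threshold: float = 0.0
    reference_variant: str | None = None  # None = lowest-information variant
    seed: int = 0


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis described by ``config``; returns the manifest.

    Deterministic given the config (the only stochastic stage would be a
    simulation, which is seeded). Inputs are never mutated; every output
    lands under ``config.output_dir`` and is listed in ``manifest.json``
    together with the input hashes and convention switches.
    """
    if config.binding_input is None:
        raise ValueError("config.binding_input is required")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {k: (dict(v) if isinstance(v, Mapping) else v) for k, v in asdict(config).items()},
        "inputs": {},
        "outputs": [],
        "stages": [],
    }

    def stage(name: str, start: float) -> None:
        elapsed = time.perf_counter() - start
        manifest["stages"].append({"name": name, "seconds": round(elapsed, 4)})
        logger.info("stage=%s elapsed=%.3fs", name, elapsed)

    def emit(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", float_format="%.10g")
        manifest["outputs"].append(name)

    t0 = time.perf_counter()
    binding_path = Path(config.binding_input)
    if binding_path.is_dir():
        for p in sorted(binding_path.glob("*.tsv")):
            manifest["inputs"][str(p)] = _sha256(p)
    else:
        manifest["inputs"][str(binding_path)] = _sha256(binding_path)
    supp = tfio.read_binding_workbook(binding_path, temperature_K=config.temperature_K)
    stage("load", t0)

    t0 = time.perf_counter()
    analyses: dict[str, VariantAnalysis] = {}
    summary_rows = []
    for variant, bt in supp.binding_tables.items():
        va = analyze_binding_table(
            bt,
            ri_pseudocount=config.ri_pseudocount,
            threshold=config.ri_threshold,
            boundary_method=config.boundary_method,
        )
        analyses[variant] = va
        emit(
            boundary_report(va.scores, va.ddg, threshold=config.ri_threshold),
            f"boundary_{variant}.tsv",
        )
        emit(va.energy_matrix.ddg.rename_axis("pos"), f"energy_matrix_{variant}.tsv")
        summary_rows.append(
            {
                "variant": variant,
                "dg_ns_kj_mol": va.boundary.dg_ns,
                "rseq_energy_bits": va.information_bits,
                "boundary_method": va.boundary.method,
                "trustworthy": va.boundary.trustworthy,
            }
        )
    stage("energetics", t0)

    t0 = time.perf_counter()
    invivo: dict[str, FrequencyMatrix] = dict(supp.frequency_matrices)
    for variant, peak_path in config.peak_tables.items():
        manifest["inputs"][str(peak_path)] = _sha256(Path(peak_path))
        ct = tfio.read_peak_table(peak_path)
        logo = selection_logo(ct, blank_fixed=True)
        invivo[variant] = logo.frequencies
        emit(logo.heights.rename_axis("pos"), f"selection_logo_{variant}.tsv")
    summary = pd.DataFrame(summary_rows).set_index("variant")
    if invivo:
        core = list(next(iter(analyses.values())).frequencies.positions)
        invivo_bits = {}
        for variant, fm in invivo.items():
            usable = [p for p in core if p in fm.positions]
            res = information_content(fm, position_range=usable, apply_correction=False)
            invivo_bits[variant] = res.total
        summary["rseq_invivo_bits"] = pd.Series(invivo_bits)
        summary["rseq_invivo_over_dgns"] = (
            summary["rseq_invivo_bits"] / summary["dg_ns_kj_mol"]
        )
    emit(summary, "specificity_summary.tsv")
    stage("logos", t0)

    t0 = time.perf_counter()
    kld_kwargs = dict(
        pseudocount=config.kld_pseudocount,
        symmetrize=config.kld_symmetrize,
        aggregate=config.kld_aggregate,
        log_base=config.kld_log_base,
    )
    matrices = {v: a.frequencies for v, a in analyses.items()}
    if len(matrices) >= 2:
        emit(pairwise_kld(matrices, **kld_kwargs), "kld_energy_models.tsv")
    if len(invivo) >= 2:
        core = list(next(iter(analyses.values())).frequencies.positions)
        aligned = {}
        for v, fm in invivo.items():
            usable = [p for p in core if p in fm.positions]
            if len(usable) >= 2:
                aligned[v] = fm.select(usable)
        if len(aligned) >= 2:
            emit(pairwise_kld(aligned, **kld_kwargs), "kld_invivo_models.tsv")
    stage("compare", t0)

    t0 = time.perf_counter()
    reference = config.reference_variant
    if reference is None and analyses:
        reference = min(analyses, key=lambda v: analyses[v].information_bits)
    if reference is not None and len(analyses) >= 2:
        ref_scores = analyses[reference].scores
        rows = []
        for variant, va in analyses.items():
            if variant == reference:
                continue
            q = overlap_quadrants(ref_scores, va.scores, threshold=config.ri_threshold)
            rows.append(
                {
                    "reference": reference,
                    "variant": variant,
                    "shared_specific": len(q.shared_specific),
                    "neither": len(q.neither),
                    "only_reference": len(q.only_a),
                    "only_variant": len(q.only_b),
                    "r2": q.r2,
                }
            )
        emit(pd.DataFrame(rows).set_index("variant"), "overlap_summary.tsv")
    stage("overlap", t0)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
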