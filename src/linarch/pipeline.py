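"""End-to-end analysis: orient, measure TIRs, classify telomeres, fold ends,
scan parS, delineate the origin island and aggregate cohort statistics.

``analyze_replicon`` runs every stage on one replicon and degrades
gracefully: a missing marker or anchor records an error string for that
stage and leaves the metric None instead of aborting, because real cohorts
contain plasmids without parAB or dnaA.  ``run_pipeline`` maps the analysis
over a set of genomes and writes the report bundle (JSON summary, TSV
tables, BED intervals and a manifest with input checksums).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import __version__
from .architecture import (
    CohortSummary,
    MissingAnchorError,
    RepliconSummary,
    delineate_island,
    locate_oric,
    pars_statistics,
    summarize_cohort,
)
from .io import LocatedFeature, read_replicon, write_features
from .orientation import UnorientableError, orient
from .parsscan import WeightMatrix, genome_background, load_default_matrix, scan
from .records import RepliconRecord
from .stemloop import FoldConfig, StemLoopStructure, fold_end, hairpin_census
from .telomeres import TelomereAssignment, classify_replicon, extract_end, load_panel
from .tir import imperfect_tir

__all__ = ["RunConfig", "RepliconReport", "analyze_replicon", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run."""

    matrix_path: Optional[str] = None
    pars_threshold: float = 15.0
    background_mode: str = "genome"  # or "uniform"
    telomere_min_identity: float = 76.0
    telomere_min_coverage: float = 19.0
    telomere_panel_path: Optional[str] = None
    fold_dmax: int = 20
    tir_min_identity: float = 90.0
    island_search_window: int = 200_000
    plasmid_max_length: int = 1_000_000  # replicons below this are plasmids
    strict_orientation: bool = False
    seed: int = 0


@dataclass
class RepliconReport:
    """Full per-replicon result: summary plus stage detail."""

    summary: RepliconSummary
    record: Optional[RepliconRecord] = None
    telomere_assignments: dict[str, TelomereAssignment] = field(default_factory=dict)
    folds: dict[str, StemLoopStructure] = field(default_factory=dict)
    hits: list = field(default_factory=list)


def analyze_replicon(
    rec: RepliconRecord,
    cfg: RunConfig = RunConfig(),
    matrix: Optional[WeightMatrix] = None,
    keep_record: bool = False,
) -> RepliconReport:
    """Run all stages on one replicon, recording per-stage failures."""
    kind = "plasmid" if rec.length < cfg.plasmid_max_length else "chromosome"
    summary = RepliconSummary(rec.id, rec.length, kind=kind)
    report = RepliconReport(summary=summary)

    try:
        oriented, decision = orient(rec, strict=cfg.strict_orientation)
        summary.oriented = True
        if decision.confidence[1] == 0:
            summary.errors["orientation"] = (
                f"unorientable replicon {rec.id}: no markers; left as input"
            )
    except UnorientableError as exc:
        summary.errors["orientation"] = str(exc)
        oriented = rec
    rec = oriented
    if keep_record:
        report.record = rec

    try:
        tir = imperfect_tir(rec, min_identity=cfg.tir_min_identity)
        summary.tir_perfect = tir.perfect_len
        summary.tir_imperfect = tir.imperfect_len
    except ValueError as exc:
        summary.errors["tir"] = str(exc)

    try:
        panel = load_panel(cfg.telomere_panel_path)
        assignments = classify_replicon(
            rec,
            panel,
            min_identity=cfg.telomere_min_identity,
            min_coverage=cfg.telomere_min_coverage,
        )
        report.telomere_assignments = assignments
        summary.telomere_left = assignments["left"].class_id
        summary.telomere_right = assignments["right"].class_id
    except ValueError as exc:
        summary.errors["telomeres"] = str(exc)

    fold_cfg = FoldConfig(dmax=cfg.fold_dmax)
    for end in ("left", "right"):
        try:
            report.folds[end] = fold_end(extract_end(rec, end), fold_cfg)
        except ValueError as exc:
            summary.errors[f"fold_{end}"] = str(exc)

    if matrix is None:
        bg = genome_background(rec) if cfg.background_mode == "genome" else None
        matrix = load_default_matrix(background=bg)
    try:
        report.hits = scan(rec, matrix, threshold=cfg.pars_threshold)
    except ValueError as exc:
        summary.errors["pars"] = str(exc)

    try:
        oric = locate_oric(rec)
        summary.oric_pos = oric
        island = delineate_island(rec, oric, search_window=cfg.island_search_window)
        summary.island = island
        summary.pars = pars_statistics(
            report.hits, oric, island.island, rec.length
        )
    except MissingAnchorError as exc:
        summary.errors["architecture"] = str(exc)

    return report


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _summary_dict(s: RepliconSummary) -> dict:
    d = {
        "replicon_id": s.replicon_id,
        "length": s.length,
        "kind": s.kind,
        "telomere_left": s.telomere_left,
        "telomere_right": s.telomere_right,
        "tir_perfect": s.tir_perfect,
        "tir_imperfect": s.tir_imperfect,
        "oric_pos": s.oric_pos,
        "errors": s.errors,
    }
    if s.island:
        d["island"] = dataclasses.asdict(s.island)
    if s.pars:
        d["pars"] = dataclasses.asdict(s.pars)
    return d


def run_pipeline(
    inputs: Sequence[str],
    outdir: str,
    cfg: RunConfig = RunConfig(),
    input_format: str = "fasta+gff3",
) -> CohortSummary:
    """Analyse a set of genome files and write the report bundle."""
    os.makedirs(outdir, exist_ok=True)
    counts = name = None
    if cfg.matrix_path:
        from .parsscan import read_counts

        counts, name = read_counts(cfg.matrix_path)
    reports: list[RepliconReport] = []
    all_hits: list[LocatedFeature] = []
    islands: list[LocatedFeature] = []
    for path in inputs:
        rec = read_replicon(path, format=input_format)
        m = None
        if counts is not None:
            from .parsscan import UNIFORM_BACKGROUND

            bg = (
                genome_background(rec)
                if cfg.background_mode == "genome"
                else UNIFORM_BACKGROUND
            )
            m = WeightMatrix(counts, bg, name=name)
        rep = analyze_replicon(rec, cfg, matrix=m)
        reports.append(rep)
        for h in rep.hits:
            all_hits.append(
                LocatedFeature(h.replicon_id, h.start, h.start + len(h.site),
                               h.strand, "parS", h.score)
            )
        if rep.summary.island:
            a, b = rep.summary.island.island
            islands.append(
                LocatedFeature(rep.summary.replicon_id, a, b, "+", "origin_island")
            )

    valid = [r.summary for r in reports if not r.summary.errors.get("orientation")]
    if not valid:
        raise RuntimeError("no valid replicons analysed")
    cohort = summarize_cohort([r.summary for r in reports])

    write_features(all_hits, os.path.join(outdir, "pars_hits.bed"), "bed")
    write_features(islands, os.path.join(outdir, "origin_islands.bed"), "bed")
    census = hairpin_census(
        [f for r in reports for f in r.folds.values()]
    )
    with open(os.path.join(outdir, "hairpin_census.tsv"), "w") as fh:
        fh.write("loop\tcount\n")
        for loop, count in census:
            fh.write(f"{loop}\t{count}\n")
    summary_doc = {
        "replicons": [_summary_dict(r.summary) for r in reports],
        "cohort": dataclasses.asdict(cohort),
    }
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary_doc, fh, indent=1, sort_keys=True)
        fh.write("\n")
    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(cfg),
        "inputs": {os.path.basename(p): _sha256(p) for p in inputs},
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    _write_text_report(reports, cohort, os.path.join(outdir, "report.txt"))
    return cohort


def _write_text_report(reports, cohort: CohortSummary, path: str) -> None:
    lines = ["linear replicon architecture report", ""]
    for r in reports:
        s = r.summary
        lines.append(f"replicon {s.replicon_id} ({s.kind}, {s.length:,} bp)")
        lines.append(
            f"  telomeres: left={s.telomere_left or 'unclassified'} "
            f"right={s.telomere_right or 'unclassified'}"
        )
        if s.tir_perfect is not None:
            lines.append(
                f"  TIR: perfect {s.tir_perfect:,} bp, imperfect {s.tir_imperfect:,} bp"
            )
        if s.island:
            lines.append(
                f"  oriC at {s.oric_pos:,}; island "
                f"[{s.island.island[0]:,}, {s.island.island[1]:,}) "
                f"({s.island.size:,} bp, {s.island.pct_of_chromosome:.2f}% of "
                f"chromosome, midpoint at {s.island.location_pct:.2f}%)"
            )
        if s.pars and s.pars.n_sites:
            p = s.pars
            lines.append(
                f"  parS: {p.n_sites} sites, {p.pct_left:.2f}% left / "
                f"{p.pct_right:.2f}% right of oriC, {p.pct_in_island:.2f}% in island"
            )
        for stage, msg in s.errors.items():
            lines.append(f"  [{stage}] {msg}")
        lines.append("")
    lines.append("cohort means (chromosomes)")
    for k, v in sorted(cohort.means.items()):
        lo, hi = cohort.ranges[k]
        lines.append(f"  {k}: {v:,.2f} (range {lo:,.2f} - {hi:,.2f})")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
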