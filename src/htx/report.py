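"""End-to-end orchestration: one config, four stages, one cohort report.

Stages run in order — outlier expression, gene-set enrichment, fusion
pipeline, tandem duplication — sharing the same normalization; a stage
whose inputs are absent is recorded as skipped, and a stage that raises
is recorded as failed without aborting the rest of the run. Outputs are a
set of TSV tables plus a JSON report whose bytes are a deterministic
function of the config (keys sorted, floats formatted).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Optional

import numpy as np
import pandas as pd

from . import __version__
from .formats_io import (
    read_bedpe,
    read_count_matrix,
    read_fusion_candidates,
    read_gene_models,
    read_gmt,
    read_seg,
    ValidationError,
)
from .geneset_enrichment import enrich_cohort
from .outlier_expression import (
    ESDParams,
    NoiseEstimate,
    call_outliers,
    compute_size_factors,
    counts_to_depth,
)
from .fusion_pipeline import (
    DEFAULT_ETS_GENES,
    apply_primary_filters,
    build_complex_events,
    corroborate_dna,
    flag_secondary_evidence,
    summarize_fusion_load,
)
from .tandem_duplication import (
    call_genotype,
    detect_focal_gains,
    estimate_copies,
    match_duplications,
)

__all__ = ["RunConfig", "CohortReport", "run_pipeline", "median_outliers_per_sample"]


@dataclass
class RunConfig:
    """Input paths (any may be None => dependent stages skipped) plus all
    module parameters with their documented defaults."""

    counts: Optional[str] = None
    gene_models: Optional[str] = None
    gmt: Optional[str] = None
    seg: Optional[str] = None
    bedpe: Optional[str] = None
    candidates: Optional[str] = None
    noise: Optional[str] = None
    dna_coverage: Optional[str] = None
    outdir: str = "htx_out"
    seed: int = 0
    alpha: float = 0.05
    r_max: int = 15
    min_depth: float = 10.0
    recurrence_fraction: float = 1.0 / 3.0
    read_length: int = 100
    ets_genes: list[str] = field(default_factory=lambda: sorted(DEFAULT_ETS_GENES))
    max_libraries: int = 2
    min_reads: int = 5
    match_tolerance_bp: int = 10
    linking_window_bp: int = 1_000_000
    edge_tolerance_bp: int = 100_000
    min_delta_log2: float = 0.3
    min_fold: float = 2.0
    td_min_log2: float = 0.3
    td_max_length_bp: int = 5_000_000
    td_boundary_tolerance_bp: int = 10_000
    td_clonal_support: float = 50.0
    genotype_threshold: int = 50

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)


@dataclass
class CohortReport:
    samples: dict[str, dict[str, Any]]
    stages: dict[str, str]  # stage -> "ok" | "skipped" | "failed: ..."
    parameters: dict[str, Any]

    @property
    def failed_stages(self) -> list[str]:
        return [k for k, v in self.stages.items() if v.startswith("failed")]

    def to_json(self) -> str:
        def _default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, (np.bool_,)):
                return bool(o)
            raise TypeError(type(o))

        payload = {
            "version": __version__,
            "parameters": self.parameters,
            "stages": self.stages,
            "samples": self.samples,
        }
        return json.dumps(payload, sort_keys=True, indent=2, default=_default)


def median_outliers_per_sample(report: CohortReport) -> int:
    """Lower median of per-sample outlier counts (documented convention)."""
    if report.stages.get("outliers") != "ok":
        raise ValidationError("outlier stage did not run")
    counts = sorted(s["outlier_count"] for s in report.samples.values())
    if not counts:
        raise ValidationError("no samples in report")
    return int(counts[(len(counts) - 1) // 2])


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: RunConfig) -> CohortReport:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: dict[str, str] = {}
    samples: dict[str, dict[str, Any]] = {}

    def sample_entry(sid: str) -> dict[str, Any]:
        return samples.setdefault(sid, {})

    def run_stage(name: str, available: bool, fn: Callable[[], None]) -> None:
        if not available:
            stages[name] = "skipped"
            return
        try:
            fn()
            stages[name] = "ok"
        except Exception as err:  # recorded, not fatal to later stages
            stages[name] = f"failed: {err}"

    params = ESDParams(r_max=config.r_max, alpha=config.alpha)
    models = read_gene_models(config.gene_models) if config.gene_models else None

    # ---- outlier expression -------------------------------------------
    calls: list = []
    counts = None

    def stage_outliers() -> None:
        nonlocal counts
        counts = read_count_matrix(config.counts)
        sf = compute_size_factors(counts)
        depth = counts_to_depth(counts, sf, models, config.read_length)
        if config.noise:
            ndf = pd.read_csv(config.noise, sep="\t")
            noise = NoiseEstimate(
                list(ndf["sample_id"].astype(str)), ndf["depth"].to_numpy(float)
            )
            if noise.sample_ids != counts.sample_ids:
                raise ValidationError("noise samples do not match count matrix")
        else:
            noise = NoiseEstimate.zero(counts.sample_ids)
        calls.extend(
            call_outliers(
                depth, noise, params,
                min_depth=config.min_depth,
                recurrence_fraction=config.recurrence_fraction,
            )
        )
        df = pd.DataFrame(
            [
                (c.gene_id, c.sample_id, c.direction, c.esd_statistic,
                 c.critical_value, c.noise_corrected_depth)
                for c in calls
            ],
            columns=["gene_id", "sample_id", "direction", "esd_statistic",
                     "critical_value", "noise_corrected_depth"],
        )
        _write_tsv(df, outdir / "outlier_calls.tsv")
        for sid in counts.sample_ids:
            sample_entry(sid)["outlier_count"] = int(
                sum(1 for c in calls if c.sample_id == sid)
            )

    run_stage("outliers", bool(config.counts and models), stage_outliers)

    # ---- enrichment ----------------------------------------------------
    def stage_enrichment() -> None:
        collection = read_gmt(config.gmt)
        universe = counts.gene_ids
        by_sample: dict[str, set[str]] = {sid: set() for sid in counts.sample_ids}
        for c in calls:
            by_sample[c.sample_id].add(c.gene_id)
        results = enrich_cohort(by_sample, collection, universe)
        df = pd.DataFrame(
            [
                (r.sample_id, r.set_name, r.overlap, r.set_size, r.query_size,
                 r.universe_size, r.p_value, r.p_bh, r.pathway_score, r.shown)
                for r in results
            ],
            columns=["sample_id", "set_name", "overlap", "set_size", "query_size",
                     "universe_size", "p_value", "p_bh", "pathway_score", "shown"],
        )
        _write_tsv(df, outdir / "enrichment.tsv")
        for sid in by_sample:
            top = [r for r in results if r.sample_id == sid and r.shown]
            top.sort(key=lambda r: (-r.pathway_score, r.set_name))
            sample_entry(sid)["top_pathways"] = [
                {"set": r.set_name, "score": round(r.pathway_score, 4)} for r in top[:5]
            ]

    run_stage("enrichment",
              stages["outliers"] == "ok" and bool(config.gmt),
              stage_enrichment)

    # ---- fusion pipeline ----------------------------------------------
    junctions = read_bedpe(config.bedpe) if config.bedpe else []

    def stage_fusions() -> None:
        cands = read_fusion_candidates(config.candidates)
        verdicts = apply_primary_filters(
            cands, config.ets_genes, config.max_libraries, config.min_reads
        )
        vdf = pd.DataFrame(
            [
                (v.candidate_id, *[v.criteria[i] for i in range(1, 6)],
                 v.retained, v.ets_exemption_applied)
                for v in verdicts
            ],
            columns=["candidate_id", "crit1_rearrangement", "crit2_recurrence",
                     "crit3_unambiguous", "crit4_repeat", "crit5_support",
                     "retained", "ets_exemption_applied"],
        )
        _write_tsv(vdf, outdir / "fusion_verdicts.tsv")
        retained = [c for c, v in zip(cands, verdicts) if v.retained]

        profiles = {p.sample_id: p for p in (read_seg(config.seg) if config.seg else [])}
        if profiles:
            flags = flag_secondary_evidence(
                retained, profiles, {}, calls, models,
                config.edge_tolerance_bp, config.min_delta_log2, config.min_fold,
            )
            fdf = pd.DataFrame(
                [
                    (f.candidate_id, f.cna_edge, f.differential_exon_expression,
                     f.outlier_3prime, f.prioritized)
                    for f in flags
                ],
                columns=["candidate_id", "cna_edge", "differential_exon_expression",
                         "outlier_3prime", "prioritized"],
            )
            _write_tsv(fdf, outdir / "fusion_priorities.tsv")

        if junctions and config.dna_coverage:
            cov_df = pd.read_csv(config.dna_coverage, sep="\t")
            coverage = dict(zip(cov_df["sample_id"].astype(str), cov_df["coverage"]))
            corr = corroborate_dna(retained, junctions, coverage, config.match_tolerance_bp)
            cdf = pd.DataFrame(
                [(c.candidate_id, c.evaluable, c.matched_breakpoint_id or "") for c in corr],
                columns=["candidate_id", "evaluable", "matched_breakpoint_id"],
            )
            _write_tsv(cdf, outdir / "fusion_dna_corroboration.tsv")

        events = []
        if junctions and models:
            by_sample_j: dict[str, list] = {}
            for j in junctions:
                by_sample_j.setdefault(j.sample_id, []).append(j)
            for sid in sorted(by_sample_j):
                events.extend(
                    build_complex_events(
                        by_sample_j[sid], models, cands,
                        config.linking_window_bp,
                        match_tolerance_bp=config.match_tolerance_bp,
                    )
                )
            edf = pd.DataFrame(
                [
                    (e.event_id, e.sample_id, jid, ";".join(e.genes),
                     ";".join(e.expressed_fusion_ids))
                    for e in events
                    for jid in e.breakpoint_ids
                ],
                columns=["event_id", "sample_id", "breakpoint_id", "genes",
                         "expressed_fusion_ids"],
            )
            _write_tsv(edf, outdir / "complex_events.tsv")

        summary = summarize_fusion_load(cands, verdicts, events, config.ets_genes)
        _write_tsv(summary, outdir / "fusion_summary.tsv")
        for row in summary.itertuples(index=False):
            entry = sample_entry(row.sample_id)
            entry["fusion_load"] = int(row.fusion_load)
            entry["complex_count"] = int(row.complex_count)
            entry["ets_status"] = bool(row.ets_status)

    run_stage("fusions", bool(config.candidates), stage_fusions)

    # ---- tandem duplications ------------------------------------------
    def stage_tandemdup() -> None:
        profiles = read_seg(config.seg)
        by_sample_j: dict[str, list] = {}
        for j in junctions:
            by_sample_j.setdefault(j.sample_id, []).append(j)
        td_rows, gt_rows = [], []
        for p in profiles:
            gains = detect_focal_gains(p, config.td_min_log2, config.td_max_length_bp)
            tds = match_duplications(
                gains, by_sample_j.get(p.sample_id, []),
                config.td_boundary_tolerance_bp, config.td_min_log2,
            )
            estimate_copies(tds, clonal_support_reference=config.td_clonal_support)
            genotype = call_genotype(tds, gains, p.sample_id, config.genotype_threshold)
            for t in tds:
                td_rows.append(
                    (t.td_id, p.sample_id, t.chrom, t.start, t.end,
                     "" if t.estimated_copies is None else round(t.estimated_copies, 4),
                     t.subclonal, t.nested_parent or "",
                     t.gain is not None)
                )
            gt_rows.append(
                (p.sample_id, genotype.n_tandem_duplications,
                 genotype.n_focal_gains, genotype.is_duplicator)
            )
            entry = sample_entry(p.sample_id)
            entry["n_tandem_duplications"] = genotype.n_tandem_duplications
            entry["is_duplicator"] = genotype.is_duplicator
        _write_tsv(
            pd.DataFrame(
                td_rows,
                columns=["td_id", "sample_id", "chrom", "start", "end",
                         "estimated_copies", "subclonal", "nested_parent",
                         "has_coverage_evidence"],
            ),
            outdir / "tandem_duplications.tsv",
        )
        _write_tsv(
            pd.DataFrame(
                gt_rows,
                columns=["sample_id", "n_tandem_duplications", "n_focal_gains",
                         "is_duplicator"],
            ),
            outdir / "duplicator_genotype.tsv",
        )

    run_stage("tandemdup", bool(config.seg and config.bedpe), stage_tandemdup)

    parameters = {k: v for k, v in vars(config).items() if not k.startswith("_")}
    report = CohortReport(samples=samples, stages=stages, parameters=parameters)
    (outdir / "report.json").write_text(report.to_json() + "\n")
    return report
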