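"""Fusion-transcript filtering, DNA corroboration, complex-rearrangement
reconstruction, gene-effect classification and reading-frame assessment.

The primary filter cascade keeps a chimeric-RNA candidate only if it
(1) arose from genome rearrangement rather than readthrough, (2) recurs in
at most ``max_libraries`` libraries (waived for ETS-family fusions, which
are genuinely recurrent in prostate cancer), (3) maps unambiguously on
both sides, (4) does not map entirely to repetitive elements, and
(5) is supported by more than ``min_reads`` split plus spanning reads.
Retained candidates are then prioritized by secondary evidence (copy-number
aberration edges, differential exon expression across the junction, outlier
expression of the 3' partner) and corroborated against DNA junctions.
Complex rearrangements (chromoplexy-like chains) are reconstructed as
connected components of a breakpoint graph and must involve more than two
genome breakpoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from .formats_io import (
    BreakpointPair,
    CopySegmentProfile,
    FusionCandidate,
    GeneModel,
    ValidationError,
)
from .outlier_expression import OutlierCall

__all__ = [
    "DEFAULT_ETS_GENES",
    "FilterVerdict",
    "PriorityFlags",
    "DnaCorroboration",
    "ComplexEvent",
    "GeneEffect",
    "FrameStatus",
    "apply_primary_filters",
    "flag_secondary_evidence",
    "corroborate_dna",
    "build_complex_events",
    "classify_gene_effects",
    "assess_frame",
    "summarize_fusion_load",
]

DEFAULT_ETS_GENES = frozenset({"ERG", "ETV1", "ETV4", "ETV5", "FLI1"})


@dataclass
class FilterVerdict:
    candidate_id: str
    criteria: dict[int, bool]  # criterion number (1..5) -> pass
    retained: bool
    ets_exemption_applied: bool


@dataclass
class PriorityFlags:
    candidate_id: str
    cna_edge: Optional[bool]
    differential_exon_expression: Optional[bool]
    outlier_3prime: Optional[bool]
    prioritized: bool


@dataclass
class DnaCorroboration:
    candidate_id: str
    evaluable: bool
    matched_breakpoint_id: Optional[str]


@dataclass
class ComplexEvent:
    event_id: str
    sample_id: str
    breakpoint_ids: list[str]
    genes: list[str]
    expressed_fusion_ids: list[str]

    @property
    def n_breakpoints(self) -> int:
        return len(self.breakpoint_ids)


@dataclass
class GeneEffect:
    gene_id: str
    event_id: str
    effect: str  # "disrupted" | "activating" | "neutral"


@dataclass
class FrameStatus:
    candidate_id: str
    status: str  # "in_frame" | "out_of_frame" | "undetermined"


# ---------------------------------------------------------------------------
# Primary filters
# ---------------------------------------------------------------------------


def apply_primary_filters(
    candidates: Sequence[FusionCandidate],
    ets_genes: Iterable[str] = DEFAULT_ETS_GENES,
    max_libraries: int = 2,
    min_reads: int = 5,
) -> list[FilterVerdict]:
    """Evaluate the five primary criteria on every candidate.

    Criterion 2 counts the distinct libraries in which the same ordered
    (gene5, gene3) pair is predicted; ETS-partnered candidates are exempt
    from it (and only from it).
    """
    ets = frozenset(ets_genes)
    libs_per_pair: dict[tuple[str, str], set[str]] = {}
    for c in candidates:
        libs_per_pair.setdefault((c.gene5, c.gene3), set()).add(c.library_id)

    verdicts: list[FilterVerdict] = []
    for c in candidates:
        n_libs = len(libs_per_pair[(c.gene5, c.gene3)])
        is_ets = c.gene5 in ets or c.gene3 in ets
        crit = {
            1: not c.is_readthrough,
            2: n_libs <= max_libraries,
            3: not c.multimapping,
            4: c.repeat_fraction < 1.0,
            5: c.total_support > min_reads,
        }
        exemption = is_ets and not crit[2]
        retained = crit[1] and (crit[2] or exemption) and crit[3] and crit[4] and crit[5]
        verdicts.append(FilterVerdict(c.id, crit, retained, exemption))
    return verdicts


# ---------------------------------------------------------------------------
# Secondary prioritization
# ---------------------------------------------------------------------------


def _near_cn_edge(
    profile: CopySegmentProfile,
    chrom: str,
    pos: int,
    tolerance_bp: int,
    min_delta: float,
) -> bool:
    segs = [s for s in profile.segments if s[0] == chrom]
    for (c0, s0, e0, r0), (c1, s1, e1, r1) in zip(segs, segs[1:]):
        if abs(r1 - r0) >= min_delta and abs(pos - e0) <= tolerance_bp:
            return True
    # Profile edges bounding an aberrant segment also count as CNA edges.
    for c0, s0, e0, r0 in segs:
        if abs(r0) >= min_delta and min(abs(pos - s0), abs(pos - e0)) <= tolerance_bp:
            return True
    return False


def _differential_exons(
    gene: GeneModel,
    pos: int,
    retained_left: bool,
    exon_depth: Mapping[tuple[str, int], Mapping[str, float]],
    sample: str,
    min_fold: float,
) -> Optional[bool]:
    left: list[float] = []
    right: list[float] = []
    found = False
    for idx in range(len(gene.exons)):
        per_sample = exon_depth.get((gene.gene_id, idx))
        if per_sample is None or sample not in per_sample:
            continue
        found = True
        s, e = gene.exons[idx]
        mid = (s + e) // 2
        (left if mid < pos else right).append(per_sample[sample])
    if not found or not left or not right:
        return None
    retained = float(np.mean(left if retained_left else right))
    lost = float(np.mean(right if retained_left else left))
    hi, lo = max(retained, lost), min(retained, lost)
    if lo == 0:
        return hi > 0
    return bool(hi / lo >= min_fold)


def flag_secondary_evidence(
    candidates: Sequence[FusionCandidate],
    profiles: Mapping[str, CopySegmentProfile],
    exon_depth: Mapping[tuple[str, int], Mapping[str, float]],
    outliers: Sequence[OutlierCall],
    models: Mapping[str, GeneModel] | None = None,
    edge_tolerance_bp: int = 100_000,
    min_delta_log2: float = 0.3,
    min_fold: float = 2.0,
) -> list[PriorityFlags]:
    """Attach secondary-evidence flags to retained candidates.

    ``exon_depth`` maps (gene_id, exon_index) to per-sample mean depth.
    A flag is ``None`` (undetermined) when its inputs are missing for that
    candidate; undetermined flags never count toward prioritization.
    """
    models = models or {}
    up_outliers = {(o.gene_id, o.sample_id) for o in outliers if o.direction == "up"}
    flags: list[PriorityFlags] = []
    for c in candidates:
        profile = profiles.get(c.library_id)
        if profile is None:
            cna: Optional[bool] = None
        else:
            cna = any(
                _near_cn_edge(profile, end.chrom, end.pos, edge_tolerance_bp, min_delta_log2)
                for end in (c.end5, c.end3)
            )
        diff: Optional[bool] = None
        for gene_id, end in ((c.gene5, c.end5), (c.gene3, c.end3)):
            model = models.get(gene_id)
            if model is None:
                continue
            verdict = _differential_exons(
                model, end.pos, end.orientation == "+", exon_depth, c.library_id, min_fold
            )
            if verdict is not None:
                diff = verdict if diff is None else (diff or verdict)
        out3 = (c.gene3, c.library_id) in up_outliers
        prioritized = bool(cna) or bool(diff) or out3
        flags.append(PriorityFlags(c.id, cna, diff, out3, prioritized))
    return flags


# ---------------------------------------------------------------------------
# DNA corroboration
# ---------------------------------------------------------------------------


def _ends_match(a, b, tol: int) -> bool:
    return a.chrom == b.chrom and a.orientation == b.orientation and abs(a.pos - b.pos) <= tol


def junction_matches_candidate(j: BreakpointPair, c: FusionCandidate, tol: int) -> bool:
    return (_ends_match(j.endA, c.end5, tol) and _ends_match(j.endB, c.end3, tol)) or (
        _ends_match(j.endA, c.end3, tol) and _ends_match(j.endB, c.end5, tol)
    )


def corroborate_dna(
    candidates: Sequence[FusionCandidate],
    junctions: Sequence[BreakpointPair],
    coverage: Mapping[str, float],
    match_tolerance_bp: int = 10,
    min_coverage: float = 5.0,
) -> list[DnaCorroboration]:
    """Mark candidates evaluable (paired DNA coverage > 5x) and matched.

    A candidate is matched when some junction in the same library has both
    ends within ``match_tolerance_bp`` of the candidate's genomic
    breakpoints with compatible orientations.
    """
    by_sample: dict[str, list[BreakpointPair]] = {}
    for j in junctions:
        by_sample.setdefault(j.sample_id, []).append(j)
    out: list[DnaCorroboration] = []
    for c in candidates:
        cov = coverage.get(c.library_id, 0.0)
        evaluable = cov > min_coverage
        matched = None
        if evaluable:
            for j in by_sample.get(c.library_id, []):
                if junction_matches_candidate(j, c, match_tolerance_bp):
                    matched = j.id
                    break
        out.append(DnaCorroboration(c.id, evaluable, matched))
    return out


# ---------------------------------------------------------------------------
# Complex rearrangements
# ---------------------------------------------------------------------------


def build_complex_events(
    junctions: Sequence[BreakpointPair],
    models: Mapping[str, GeneModel],
    candidates: Sequence[FusionCandidate] = (),
    linking_window_bp: int = 1_000_000,
    min_breakpoints: int = 3,
    match_tolerance_bp: int = 10,
) -> list[ComplexEvent]:
    """Reconstruct chromoplexy-like chains from one sample's junctions.

    Junction ends are graph nodes; the two ends of a junction are joined,
    as are ends of different junctions lying within ``linking_window_bp``
    of each other on the reference. Connected components containing at
    least ``min_breakpoints`` junctions (the ">2 genome breakpoints" rule)
    become events; expressed fusions are attached when a member junction
    coincides with a candidate's breakpoints.
    """
    g = nx.Graph()
    ends = []
    for j in junctions:
        g.add_edge((j.id, "A"), (j.id, "B"))
        ends.append(((j.id, "A"), j.endA))
        ends.append(((j.id, "B"), j.endB))
    for i, (node_i, end_i) in enumerate(ends):
        for node_j, end_j in ends[i + 1 :]:
            if node_i[0] == node_j[0]:
                continue
            if end_i.chrom == end_j.chrom and abs(end_i.pos - end_j.pos) <= linking_window_bp:
                g.add_edge(node_i, node_j)

    by_id = {j.id: j for j in junctions}
    events: list[ComplexEvent] = []
    for comp in sorted(nx.connected_components(g), key=lambda c: sorted(c)[0]):
        member_ids = sorted({jid for jid, _ in comp})
        if len(member_ids) < min_breakpoints:
            continue
        sample = by_id[member_ids[0]].sample_id
        genes = set()
        for jid in member_ids:
            for end in (by_id[jid].endA, by_id[jid].endB):
                for m in models.values():
                    if m.chrom == end.chrom and m.contains(end.pos):
                        genes.add(m.gene_id)
        expressed = sorted(
            {
                c.id
                for c in candidates
                if c.library_id == sample
                and any(
                    junction_matches_candidate(by_id[jid], c, match_tolerance_bp)
                    for jid in member_ids
                )
            }
        )
        events.append(
            ComplexEvent(
                event_id=f"{sample}_ce{len(events) + 1}",
                sample_id=sample,
                breakpoint_ids=member_ids,
                genes=sorted(genes),
                expressed_fusion_ids=expressed,
            )
        )
    return events


# ---------------------------------------------------------------------------
# Gene effects within a complex event
# ---------------------------------------------------------------------------


def classify_gene_effects(
    event: ComplexEvent,
    models: Mapping[str, GeneModel],
    junctions: Sequence[BreakpointPair],
    frames: Mapping[str, FrameStatus],
    outliers: Sequence[OutlierCall],
    candidates: Sequence[FusionCandidate] = (),
) -> list[GeneEffect]:
    """Classify each event gene as activating, disrupted or neutral.

    Activating: the gene is the 3' partner of an in-frame expressed fusion
    of the event, or carries an up-regulated outlier call in the sample.
    Disrupted: a member breakpoint interrupts its CDS without activating
    evidence. Neutral otherwise (breakpoint in UTR/intron-flank only).
    """
    by_id = {j.id: j for j in junctions}
    cand_by_id = {c.id: c for c in candidates}
    up = {(o.gene_id, o.sample_id) for o in outliers if o.direction == "up"}
    effects: list[GeneEffect] = []
    for gene_id in event.genes:
        model = models.get(gene_id)
        if model is None:
            raise ValidationError(f"event gene {gene_id} has no model")
        activating = (gene_id, event.sample_id) in up
        for fid in event.expressed_fusion_ids:
            c = cand_by_id.get(fid)
            if c is not None and c.gene3 == gene_id:
                fr = frames.get(fid)
                if fr is not None and fr.status == "in_frame":
                    activating = True
        cds_hit = False
        if model.has_cds:
            for jid in event.breakpoint_ids:
                j = by_id[jid]
                for end in (j.endA, j.endB):
                    if end.chrom == model.chrom and model.cds_start <= end.pos < model.cds_end:
                        cds_hit = True
        if activating:
            effect = "activating"
        elif cds_hit:
            effect = "disrupted"
        else:
            effect = "neutral"
        effects.append(GeneEffect(gene_id, event.event_id, effect))
    return effects


# ---------------------------------------------------------------------------
# Reading frame
# ---------------------------------------------------------------------------


def _coding_retained_5p(model: GeneModel, pos: int) -> int:
    """Coding bases retained from the gene5 CDS start to the junction."""
    if model.strand == "+":
        return model.coding_bases_before(pos)
    return model.coding_length - model.coding_bases_before(pos)


def _coding_phase_3p(model: GeneModel, pos: int) -> int:
    """CDS phase at the gene3 junction position (bases upstream mod 3)."""
    if model.strand == "+":
        upstream = model.coding_bases_before(pos)
    else:
        upstream = model.coding_length - model.coding_bases_before(pos)
    return upstream % 3


def assess_frame(candidate: FusionCandidate, models: Mapping[str, GeneModel]) -> FrameStatus:
    """Decide whether the fusion junction preserves the reading frame.

    In frame iff both breakpoints fall within annotated CDS and the coding
    length retained from the 5' partner is congruent (mod 3) to the CDS
    phase of the 3' partner at its junction. Undetermined when either
    partner lacks CDS annotation.
    """
    m5 = models.get(candidate.gene5)
    m3 = models.get(candidate.gene3)
    if m5 is None or m3 is None:
        raise ValidationError(f"candidate {candidate.id}: partner gene without model")
    for m, end in ((m5, candidate.end5), (m3, candidate.end3)):
        if end.chrom != m.chrom or not m.contains(end.pos):
            raise ValidationError(
                f"candidate {candidate.id}: breakpoint {end.chrom}:{end.pos} "
                f"outside span of {m.gene_id}"
            )
    if not (m5.has_cds and m3.has_cds):
        return FrameStatus(candidate.id, "undetermined")
    in_cds5 = m5.cds_start <= candidate.end5.pos < m5.cds_end
    in_cds3 = m3.cds_start <= candidate.end3.pos < m3.cds_end
    if not (in_cds5 and in_cds3):
        return FrameStatus(candidate.id, "out_of_frame")
    retained = _coding_retained_5p(m5, candidate.end5.pos)
    phase = _coding_phase_3p(m3, candidate.end3.pos)
    status = "in_frame" if retained % 3 == phase else "out_of_frame"
    return FrameStatus(candidate.id, status)


# ---------------------------------------------------------------------------
# Per-sample summary
# ---------------------------------------------------------------------------


def summarize_fusion_load(
    candidates: Sequence[FusionCandidate],
    verdicts: Sequence[FilterVerdict],
    events: Sequence[ComplexEvent],
    ets_genes: Iterable[str] = DEFAULT_ETS_GENES,
) -> "pd.DataFrame":
    """Per-sample fusion load, complex-event count and ETS status."""
    import pandas as pd

    ets = frozenset(ets_genes)
    retained_ids = {v.candidate_id for v in verdicts if v.retained}
    samples = sorted({c.library_id for c in candidates} | {e.sample_id for e in events})
    rows = []
    for s in samples:
        mine = [c for c in candidates if c.library_id == s and c.id in retained_ids]
        rows.append(
            {
                "sample_id": s,
                "fusion_load": len(mine),
                "complex_count": sum(1 for e in events if e.sample_id == s),
                "ets_status": any(c.gene5 in ets or c.gene3 in ets for c in mine),
            }
        )
    return pd.DataFrame(rows, columns=["sample_id", "fusion_load", "complex_count", "ets_status"])
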