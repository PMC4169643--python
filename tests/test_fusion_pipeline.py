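"""Primary filter cascade, secondary evidence, DNA corroboration, complex
rearrangements, gene effects and reading-frame arithmetic."""

import numpy as np
import pytest

from htx.formats_io import (
    BreakpointEnd,
    BreakpointPair,
    CopySegmentProfile,
    FusionCandidate,
    GeneModel,
    ValidationError,
)
from htx.fusion_pipeline import (
    apply_primary_filters,
    assess_frame,
    build_complex_events,
    classify_gene_effects,
    corroborate_dna,
    flag_secondary_evidence,
    summarize_fusion_load,
    FrameStatus,
)
from htx.outlier_expression import OutlierCall
from htx.synthetic_cohort import SimConfig, simulate_complex_chain, simulate_fusion_candidates


def make_candidate(cid="fc1", lib="T1", gene5="A", gene3="B", split=5, spanning=5,
                   readthrough=False, multimap=False, repeat=0.0,
                   end5=None, end3=None):
    return FusionCandidate(
        id=cid, library_id=lib, gene5=gene5, gene3=gene3,
        end5=end5 or BreakpointEnd("chr1", 1_000_000, "+"),
        end3=end3 or BreakpointEnd("chr2", 2_000_000, "-"),
        split_reads=split, spanning_reads=spanning,
        is_readthrough=readthrough, multimapping=multimap, repeat_fraction=repeat,
    )


# ---------------------------------------------------------------------------
# Primary filters
# ---------------------------------------------------------------------------


class TestPrimaryFilters:
    @pytest.mark.parametrize(
        "split,spanning,passes", [(3, 3, True), (3, 2, False), (6, 0, True), (0, 5, False)]
    )
    def test_support_boundary(self, split, spanning, passes):
        (v,) = apply_primary_filters([make_candidate(split=split, spanning=spanning)])
        assert v.criteria[5] is passes
        assert v.retained is passes

    def test_readthrough_fails_criterion_one(self):
        (v,) = apply_primary_filters([make_candidate(readthrough=True)])
        assert not v.criteria[1] and not v.retained

    def test_multimapping_fails_criterion_three(self):
        (v,) = apply_primary_filters([make_candidate(multimap=True)])
        assert not v.criteria[3] and not v.retained

    @pytest.mark.parametrize("repeat,passes", [(1.0, False), (0.99, True)])
    def test_repeat_entirely_means_exactly_one(self, repeat, passes):
        (v,) = apply_primary_filters([make_candidate(repeat=repeat)])
        assert v.criteria[4] is passes

    def test_recurrence_counts_distinct_libraries(self):
        cands = [
            make_candidate(cid=f"fc{i}", lib=f"L{i}", gene5="X", gene3="Y")
            for i in range(3)
        ]
        verdicts = apply_primary_filters(cands)
        assert all(not v.criteria[2] and not v.retained for v in verdicts)

    def test_ets_exemption_waives_only_recurrence(self):
        recurrent = [
            make_candidate(cid=f"e{i}", lib=f"L{i}", gene5="TMPRSS2", gene3="ERG")
            for i in range(15)
        ]
        verdicts = apply_primary_filters(recurrent)
        assert all(v.retained and v.ets_exemption_applied for v in verdicts)
        # An ETS candidate failing another criterion is never rescued.
        weak = [
            make_candidate(cid=f"w{i}", lib=f"L{i}", gene5="TMPRSS2", gene3="ERG",
                           split=1, spanning=1)
            for i in range(15)
        ]
        assert all(not v.retained for v in apply_primary_filters(weak))

    def test_synthetic_truth_recovered_exactly(self):
        cands, _, truth = simulate_fusion_candidates(SimConfig(seed=7))
        verdicts = apply_primary_filters(cands)
        retained = {v.candidate_id for v in verdicts if v.retained}
        truths = {c for c, lab in truth.fusion_labels.items() if lab.startswith("true")}
        assert retained == truths
        # Every artifact fails exactly its designed criterion.
        fail_map = {
            "readthrough": 1, "recurrent_artifact": 2, "multimap_artifact": 3,
            "repeat_artifact": 4, "low_support": 5,
        }
        for v in verdicts:
            label = truth.fusion_labels[v.candidate_id]
            if label in fail_map:
                failed = [i for i in range(1, 6) if not v.criteria[i]]
                assert failed == [fail_map[label]]


# ---------------------------------------------------------------------------
# Secondary evidence
# ---------------------------------------------------------------------------


class TestSecondaryEvidence:
    def test_cna_edge_within_tolerance(self):
        profile = CopySegmentProfile(
            "T1", [("chr1", 0, 950_000, 0.0), ("chr1", 950_000, 3_000_000, 1.0)]
        )
        c = make_candidate(end5=BreakpointEnd("chr1", 1_000_000, "+"))  # 50 kb away
        (f,) = flag_secondary_evidence([c], {"T1": profile}, {}, [])
        assert f.cna_edge is True and f.prioritized

    def test_cna_edge_outside_tolerance(self):
        profile = CopySegmentProfile(
            "T1", [("chr1", 0, 500_000, 0.0), ("chr1", 500_000, 3_000_000, 1.0)]
        )
        c = make_candidate(end5=BreakpointEnd("chr1", 1_000_000, "+"),
                           end3=BreakpointEnd("chr9", 5_000_000, "-"))
        (f,) = flag_secondary_evidence([c], {"T1": profile}, {}, [])
        assert f.cna_edge is False

    def test_differential_exon_expression(self):
        gene3 = GeneModel("B", "chr2", "+",
                          [(1_990_000, 1_995_000), (2_005_000, 2_010_000)])
        exon_depth = {("B", 0): {"T1": 2.0}, ("B", 1): {"T1": 20.0}}
        c = make_candidate(end3=BreakpointEnd("chr2", 2_000_000, "-"))
        (f,) = flag_secondary_evidence([c], {}, exon_depth, [], {"B": gene3})
        assert f.differential_exon_expression is True

    def test_outlier_3prime_flag(self):
        call = OutlierCall("B", "T1", "up", 5.0, 3.0, 60.0)
        (f,) = flag_secondary_evidence([make_candidate()], {}, {}, [call])
        assert f.outlier_3prime is True and f.prioritized

    def test_missing_inputs_undetermined_not_fatal(self):
        (f,) = flag_secondary_evidence([make_candidate()], {}, {}, [])
        assert f.cna_edge is None and f.differential_exon_expression is None
        assert f.prioritized is False


# ---------------------------------------------------------------------------
# DNA corroboration
# ---------------------------------------------------------------------------


class TestCorroboration:
    def _junction_for(self, c, jid="j1", tol_shift=0):
        return BreakpointPair(
            jid,
            BreakpointEnd(c.end5.chrom, c.end5.pos + tol_shift, c.end5.orientation),
            BreakpointEnd(c.end3.chrom, c.end3.pos, c.end3.orientation),
            20, c.library_id,
        )

    @pytest.mark.parametrize("cov,evaluable", [(4.9, False), (5.0, False), (5.1, True)])
    def test_coverage_boundary(self, cov, evaluable):
        c = make_candidate()
        (r,) = corroborate_dna([c], [self._junction_for(c)], {"T1": cov})
        assert r.evaluable is evaluable
        assert (r.matched_breakpoint_id is not None) == evaluable

    def test_artifact_without_junction_unmatched(self):
        c = make_candidate()
        (r,) = corroborate_dna([c], [], {"T1": 23.0})
        assert r.evaluable and r.matched_breakpoint_id is None

    def test_raising_tolerance_never_unmatches(self):
        c = make_candidate()
        j = self._junction_for(c, tol_shift=8)
        for tol in (8, 20, 100, 10_000):
            (r,) = corroborate_dna([c], [j], {"T1": 23.0}, match_tolerance_bp=tol)
            assert r.matched_breakpoint_id == "j1"
        (r,) = corroborate_dna([c], [j], {"T1": 23.0}, match_tolerance_bp=7)
        assert r.matched_breakpoint_id is None


# ---------------------------------------------------------------------------
# Complex events
# ---------------------------------------------------------------------------


def _chain_genes(k, offset=0):
    return [
        GeneModel(f"CG{offset + i}", f"chr{offset + i + 1}", "+",
                  [(5_000_000, 5_080_000)])
        for i in range(k)
    ]


class TestComplexEvents:
    def test_six_breakpoint_chain_is_one_event(self, rng):
        genes = _chain_genes(6)
        junctions, fusion = simulate_complex_chain(6, genes, "S1", rng)
        models = {g.gene_id: g for g in genes}
        events = build_complex_events(junctions, models, [fusion])
        assert len(events) == 1
        assert events[0].n_breakpoints == 6
        assert events[0].genes == sorted(g.gene_id for g in genes)
        assert events[0].expressed_fusion_ids == [fusion.id]

    def test_reciprocal_pair_not_complex(self, rng):
        genes = _chain_genes(2, offset=8)
        junctions, _ = simulate_complex_chain(2, genes, "S1", rng)
        assert build_complex_events(junctions, {g.gene_id: g for g in genes}) == []

    def test_two_chains_two_disjoint_events(self, rng):
        g1, g2 = _chain_genes(4), _chain_genes(4, offset=10)
        j1, _ = simulate_complex_chain(4, g1, "S1", rng, id_prefix="a")
        j2, _ = simulate_complex_chain(4, g2, "S1", rng, id_prefix="b")
        models = {g.gene_id: g for g in g1 + g2}
        events = build_complex_events(j1 + j2, models)
        assert len(events) == 2
        members = [set(e.breakpoint_ids) for e in events]
        assert members[0].isdisjoint(members[1])
        assert sum(len(m) for m in members) == 8  # partition: nothing twice


# ---------------------------------------------------------------------------
# Gene effects
# ---------------------------------------------------------------------------


class TestGeneEffects:
    def _setup(self, rng):
        genes = _chain_genes(3)
        for g in genes:
            g.cds_start, g.cds_end = g.start, g.end  # fully coding
        junctions, fusion = simulate_complex_chain(3, genes, "S1", rng)
        models = {g.gene_id: g for g in genes}
        (event,) = build_complex_events(junctions, models, [fusion])
        return genes, junctions, fusion, models, event

    def test_cds_breakpoint_without_fusion_is_disrupted(self, rng):
        genes, junctions, fusion, models, event = self._setup(rng)
        frames = {fusion.id: FrameStatus(fusion.id, "out_of_frame")}
        effects = {e.gene_id: e.effect for e in
                   classify_gene_effects(event, models, junctions, frames, [])}
        assert set(effects.values()) == {"disrupted"}

    def test_in_frame_3prime_partner_is_activating(self, rng):
        genes, junctions, fusion, models, event = self._setup(rng)
        frames = {fusion.id: FrameStatus(fusion.id, "in_frame")}
        effects = {e.gene_id: e.effect for e in
                   classify_gene_effects(event, models, junctions, frames, [],
                                         candidates=[fusion])}
        assert effects[fusion.gene3] == "activating"

    def test_up_outlier_gene_is_activating(self, rng):
        genes, junctions, fusion, models, event = self._setup(rng)
        call = OutlierCall(genes[2].gene_id, "S1", "up", 6.0, 3.0, 50.0)
        effects = {e.gene_id: e.effect for e in
                   classify_gene_effects(event, models, junctions, {}, [call])}
        assert effects[genes[2].gene_id] == "activating"

    def test_utr_only_breakpoint_is_neutral(self, rng):
        genes = _chain_genes(3)
        # CDS confined to a region the breakpoints cannot hit.
        for g in genes:
            g.cds_start, g.cds_end = g.start + 1000, g.start + 1500
        rng2 = np.random.default_rng(0)
        junctions, fusion = simulate_complex_chain(3, genes, "S1", rng2)
        models = {g.gene_id: g for g in genes}
        (event,) = build_complex_events(junctions, models)
        effects = classify_gene_effects(event, models, junctions, {}, [])
        by_id = {x.id: x for x in junctions}
        ends = [e for jid in event.breakpoint_ids for e in
                (by_id[jid].endA, by_id[jid].endB)]
        cds_free = [
            e.effect for e in effects
            if not any(
                end.chrom == models[e.gene_id].chrom
                and models[e.gene_id].cds_start <= end.pos < models[e.gene_id].cds_end
                for end in ends
            )
        ]
        assert cds_free and all(eff == "neutral" for eff in cds_free)


# ---------------------------------------------------------------------------
# Reading frame
# ---------------------------------------------------------------------------


def _frame_pair():
    m5 = GeneModel("A", "chr1", "+", [(1000, 2000)], 1100, 1900)
    m3 = GeneModel("B", "chr2", "+", [(5000, 6000)], 5100, 5900)
    return {"A": m5, "B": m3}


def _frame_candidate(p5, p3):
    return make_candidate(end5=BreakpointEnd("chr1", p5, "+"),
                          end3=BreakpointEnd("chr2", p3, "-"))


class TestFrame:
    @pytest.mark.parametrize("phase5", [0, 1, 2])
    @pytest.mark.parametrize("phase3", [0, 1, 2])
    def test_all_phase_combinations(self, phase5, phase3):
        models = _frame_pair()
        st = assess_frame(_frame_candidate(1400 + phase5, 5401 + phase3), models)
        expected = "in_frame" if (300 + phase5) % 3 == (301 + phase3) % 3 else "out_of_frame"
        assert st.status == expected

    def test_one_nt_shift_flips_the_call(self):
        models = _frame_pair()
        assert assess_frame(_frame_candidate(1400, 5400), models).status == "in_frame"
        assert assess_frame(_frame_candidate(1401, 5400), models).status == "out_of_frame"

    def test_noncoding_partner_undetermined(self):
        models = _frame_pair()
        models["B"] = GeneModel("B", "chr2", "+", [(5000, 6000)])
        assert assess_frame(_frame_candidate(1400, 5400), models).status == "undetermined"

    def test_breakpoint_outside_span_is_error(self):
        with pytest.raises(ValidationError, match="outside"):
            assess_frame(_frame_candidate(100, 5400), _frame_pair())

    def test_translation_invariance(self):
        shift = 7_654_321
        models = _frame_pair()
        shifted = {
            gid: GeneModel(gid, m.chrom, m.strand,
                           [(s + shift, e + shift) for s, e in m.exons],
                           m.cds_start + shift, m.cds_end + shift)
            for gid, m in models.items()
        }
        for p5, p3 in [(1400, 5400), (1523, 5677), (1401, 5400)]:
            a = assess_frame(_frame_candidate(p5, p3), models).status
            b = assess_frame(_frame_candidate(p5 + shift, p3 + shift), shifted).status
            assert a == b

    def test_minus_strand_arithmetic(self):
        # Minus-strand gene5: retained coding runs from cds_end leftward.
        m5 = GeneModel("A", "chr1", "-", [(1000, 2000)], 1100, 1900)
        m3 = GeneModel("B", "chr2", "+", [(5000, 6000)], 5100, 5900)
        models = {"A": m5, "B": m3}
        # Breakpoint at 1600 retains 1900-1600 = 300 coding bases.
        c = make_candidate(end5=BreakpointEnd("chr1", 1600, "-"),
                           end3=BreakpointEnd("chr2", 5401, "-"))
        assert assess_frame(c, models).status == "out_of_frame"
        c2 = make_candidate(end5=BreakpointEnd("chr1", 1600, "-"),
                            end3=BreakpointEnd("chr2", 5400, "-"))
        assert assess_frame(c2, models).status == "in_frame"


# ---------------------------------------------------------------------------
# Summary
# ---------------------------------------------------------------------------


class TestSummary:
    def test_per_sample_load_and_ets(self, rng):
        cands = [make_candidate(cid=f"fc{i}", lib="T1") for i in range(3)]
        cands.append(make_candidate(cid="ets1", lib="T2", gene5="TMPRSS2", gene3="ERG"))
        cands.append(make_candidate(cid="rt", lib="T3", readthrough=True))
        verdicts = apply_primary_filters(cands)
        df = summarize_fusion_load(cands, verdicts, [])
        row = df.set_index("sample_id")
        assert row.loc["T1", "fusion_load"] == 3 and not row.loc["T1", "ets_status"]
        assert row.loc["T2", "fusion_load"] == 1 and row.loc["T2", "ets_status"]
        assert row.loc["T3", "fusion_load"] == 0
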