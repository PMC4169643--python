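"""Round-trip, coordinate-convention and contract tests for the readers."""

import numpy as np
import pytest

from htx.formats_io import (
    BreakpointEnd,
    BreakpointPair,
    CopySegmentProfile,
    CountMatrix,
    FormatError,
    FusionCandidate,
    GeneModel,
    GeneSetCollection,
    ValidationError,
    read_bedpe,
    read_count_matrix,
    read_fusion_candidates,
    read_gene_models,
    read_gmt,
    read_seg,
    write_bedpe,
    write_count_matrix,
    write_fusion_candidates,
    write_gene_models,
    write_gmt,
    write_seg,
)


# ---------------------------------------------------------------------------
# Count matrix
# ---------------------------------------------------------------------------


class TestCountMatrix:
    def test_read_back_identity(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("gene_id\tA\tB\ng1\t10\t20\ng2\t30\t60\n")
        cm = read_count_matrix(p)
        assert cm.gene_ids == ["g1", "g2"]
        assert cm.sample_ids == ["A", "B"]
        assert cm.counts.tolist() == [[10, 20], [30, 60]]

    def test_negative_cell_names_gene_and_sample(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("gene_id\tA\tB\ng1\t10\t-3\n")
        with pytest.raises(FormatError, match="g1.*B"):
            read_count_matrix(p)

    def test_non_integer_cell(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("gene_id\tA\ng1\t1.5\n")
        with pytest.raises(FormatError, match="non-integer"):
            read_count_matrix(p)

    def test_duplicate_gene_id(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("gene_id\tA\ng1\t1\ng1\t2\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_count_matrix(p)

    def test_round_trip(self, tmp_path):
        cm = CountMatrix(["g1", "g2"], ["s1", "s2", "s3"],
                         np.arange(6).reshape(2, 3))
        p = tmp_path / "c.tsv"
        write_count_matrix(cm, p)
        back = read_count_matrix(p)
        assert back.gene_ids == cm.gene_ids
        assert back.sample_ids == cm.sample_ids
        assert np.array_equal(back.counts, cm.counts)


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


class TestGmt:
    def test_basic_set(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("CellCycle\tdesc\tPLK1\tCDK1\n")
        coll = read_gmt(p)
        assert coll.sets["CellCycle"] == {"PLK1", "CDK1"}

    def test_duplicate_genes_deduplicated(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("S\td\tA\tA\tB\n")
        assert len(read_gmt(p).sets["S"]) == 2

    @pytest.mark.parametrize("content", ["", "OnlyName\tdesc\n"])
    def test_malformed(self, tmp_path, content):
        p = tmp_path / "s.gmt"
        p.write_text(content)
        with pytest.raises(FormatError):
            read_gmt(p)

    def test_round_trip(self, tmp_path):
        coll = GeneSetCollection({"A": frozenset({"x", "y"}), "B": frozenset({"z"})})
        p = tmp_path / "s.gmt"
        write_gmt(coll, p)
        assert read_gmt(p).sets == coll.sets


# ---------------------------------------------------------------------------
# SEG
# ---------------------------------------------------------------------------


class TestSeg:
    def test_coordinate_convention(self, tmp_path):
        p = tmp_path / "p.seg"
        p.write_text(
            "sample_id\tchrom\tstart\tend\tlog2ratio\nT1\tchr1\t1\t100\t0.5\n"
        )
        profiles = read_seg(p)
        assert profiles[0].segments == [("chr1", 0, 100, 0.5)]

    def test_interleaved_samples_grouped(self, tmp_path):
        p = tmp_path / "p.seg"
        p.write_text(
            "sample_id\tchrom\tstart\tend\tlog2ratio\n"
            "T1\tchr1\t1\t100\t0.0\nT2\tchr1\t1\t100\t0.0\nT1\tchr1\t101\t200\t1.0\n"
        )
        profiles = read_seg(p)
        assert [pr.sample_id for pr in profiles] == ["T1", "T2"]
        assert len(profiles[0].segments) == 2

    def test_overlap_rejected(self, tmp_path):
        p = tmp_path / "p.seg"
        p.write_text(
            "sample_id\tchrom\tstart\tend\tlog2ratio\n"
            "T1\tchr1\t1\t100\t0.0\nT1\tchr1\t50\t150\t1.0\n"
        )
        with pytest.raises(ValidationError, match="overlap"):
            read_seg(p)

    def test_round_trip(self, tmp_path):
        prof = CopySegmentProfile("T1", [("chr1", 0, 100, 0.5), ("chr2", 10, 60, -0.25)])
        p = tmp_path / "p.seg"
        write_seg([prof], p)
        back = read_seg(p)
        assert back[0].sample_id == "T1"
        assert [(c, s, e) for c, s, e, _ in back[0].segments] == [
            ("chr1", 0, 100), ("chr2", 10, 60)
        ]
        assert np.allclose([r for *_, r in back[0].segments], [0.5, -0.25])


# ---------------------------------------------------------------------------
# BEDPE
# ---------------------------------------------------------------------------


class TestBedpe:
    def test_strands_to_orientations_and_score(self, tmp_path):
        p = tmp_path / "j.bedpe"
        p.write_text("chr1\t100\t101\tchr2\t200\t201\tj1\t7\t+\t-\tT1\n")
        (bp,) = read_bedpe(p)
        assert bp.endA == BreakpointEnd("chr1", 100, "+")
        assert bp.endB == BreakpointEnd("chr2", 200, "-")
        assert bp.support_reads == 7
        assert bp.sample_id == "T1"

    def test_too_few_columns(self, tmp_path):
        p = tmp_path / "j.bedpe"
        p.write_text("chr1\t100\t101\tchr2\t200\t201\n")
        with pytest.raises(FormatError, match="10"):
            read_bedpe(p)

    def test_malformed_strand(self, tmp_path):
        p = tmp_path / "j.bedpe"
        p.write_text("chr1\t100\t101\tchr2\t200\t201\tj1\t7\t*\t-\n")
        with pytest.raises(FormatError, match="strand"):
            read_bedpe(p)

    def test_round_trip(self, tmp_path):
        pairs = [
            BreakpointPair("j1", BreakpointEnd("chr1", 5, "+"),
                           BreakpointEnd("chr1", 500, "-"), 12, "T1"),
            BreakpointPair("j2", BreakpointEnd("chr3", 7, "-"),
                           BreakpointEnd("chr4", 9, "+"), 0, "T2"),
        ]
        p = tmp_path / "j.bedpe"
        write_bedpe(pairs, p)
        assert read_bedpe(p) == pairs


# ---------------------------------------------------------------------------
# Fusion candidates
# ---------------------------------------------------------------------------


def _candidate(**kw) -> FusionCandidate:
    base = dict(
        id="fc1", library_id="T1", gene5="A", gene3="B",
        end5=BreakpointEnd("chr1", 100, "+"), end3=BreakpointEnd("chr2", 200, "-"),
        split_reads=3, spanning_reads=4, is_readthrough=False,
        multimapping=False, repeat_fraction=0.25,
    )
    base.update(kw)
    return FusionCandidate(**base)


class TestFusionTable:
    def test_round_trip_preserves_all_fields(self, tmp_path):
        cands = [_candidate(), _candidate(id="fc2", is_readthrough=True, repeat_fraction=1.0)]
        p = tmp_path / "f.tsv"
        write_fusion_candidates(cands, p)
        assert read_fusion_candidates(p) == cands

    def test_total_support(self):
        assert _candidate(split_reads=3, spanning_reads=4).total_support == 7

    def test_repeat_fraction_out_of_range(self, tmp_path):
        p = tmp_path / "f.tsv"
        write_fusion_candidates([_candidate()], p)
        text = p.read_text().replace("0.250000", "1.2")
        p.write_text(text)
        with pytest.raises(FormatError, match="repeat_fraction"):
            read_fusion_candidates(p)

    def test_missing_column_named(self, tmp_path):
        p = tmp_path / "f.tsv"
        write_fusion_candidates([_candidate()], p)
        lines = p.read_text().splitlines()
        cols = lines[0].split("\t")
        idx = cols.index("spanning_reads")
        out = ["\t".join(c for i, c in enumerate(ln.split("\t")) if i != idx) for ln in lines]
        p.write_text("\n".join(out) + "\n")
        with pytest.raises(FormatError, match="spanning_reads"):
            read_fusion_candidates(p)


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------


class TestGeneModels:
    def test_round_trip_with_cds(self, tmp_path):
        models = {
            "A": GeneModel("A", "chr1", "+", [(100, 200), (300, 400)], 150, 350),
            "B": GeneModel("B", "chr2", "-", [(1000, 1500)]),
        }
        p = tmp_path / "g.gtf"
        write_gene_models(models, p)
        back = read_gene_models(p)
        assert back["A"].exons == [(100, 200), (300, 400)]
        assert (back["A"].cds_start, back["A"].cds_end) == (150, 350)
        assert back["B"].strand == "-" and not back["B"].has_cds

    def test_gene_length_is_exon_sum(self):
        g = GeneModel("A", "chr1", "+", [(0, 100), (200, 250)])
        assert g.gene_length == 150

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            GeneModel("A", "chr1", "+", [(0, 100), (50, 150)])

    def test_cds_outside_exon_span_rejected(self):
        with pytest.raises(ValidationError):
            GeneModel("A", "chr1", "+", [(100, 200)], 50, 150)
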