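"""Readers and writers for the tabular formats the pipeline consumes.

All internal coordinates are 0-based half-open. On disk, SEG and GTF are
1-based inclusive (converted on read/write); BEDPE is already 0-based
half-open. Every reader validates its input and raises :class:`FormatError`
or :class:`ValidationError` with enough context to locate the offending
record; every reader/writer pair round-trips valid files.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "CountMatrix",
    "GeneModel",
    "GeneSetCollection",
    "CopySegmentProfile",
    "BreakpointEnd",
    "BreakpointPair",
    "FusionCandidate",
    "read_count_matrix",
    "write_count_matrix",
    "read_gmt",
    "write_gmt",
    "read_seg",
    "write_seg",
    "read_bedpe",
    "write_bedpe",
    "read_fusion_candidates",
    "write_fusion_candidates",
    "read_gene_models",
    "write_gene_models",
]


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class ValidationError(ValueError):
    """Parsed values violate a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Gene x sample matrix of raw read counts.

    The substrate of normalization and outlier calling: ``counts[i, j]`` is
    the number of reads assigned to gene ``gene_ids[i]`` in library
    ``sample_ids[j]``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids in count matrix")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample ids in count matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValidationError("counts must be integral")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count for gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class GeneModel:
    """Simplified gene model: sorted, non-overlapping exons plus optional CDS bounds."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"{self.gene_id}: strand must be + or -")
        ex = sorted((int(s), int(e)) for s, e in self.exons)
        for (s, e) in ex:
            if e <= s:
                raise ValidationError(f"{self.gene_id}: empty exon ({s}, {e})")
        for (_, e0), (s1, _) in zip(ex, ex[1:]):
            if s1 < e0:
                raise ValidationError(f"{self.gene_id}: overlapping exons")
        self.exons = ex
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValidationError(f"{self.gene_id}: CDS bounds must both be set or both absent")
        if self.cds_start is not None:
            if not (ex[0][0] <= self.cds_start < self.cds_end <= ex[-1][1]):
                raise ValidationError(f"{self.gene_id}: CDS outside exon span")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def gene_length(self) -> int:
        """Sum of exon lengths in bp (the denominator of depth conversion)."""
        return sum(e - s for s, e in self.exons)

    @property
    def has_cds(self) -> bool:
        return self.cds_start is not None

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def coding_bases_before(self, pos: int) -> int:
        """Coding bases genomically left of ``pos`` (exonic, within CDS bounds)."""
        if not self.has_cds:
            raise ValidationError(f"{self.gene_id}: no CDS annotation")
        total = 0
        for s, e in self.exons:
            lo = max(s, self.cds_start)
            hi = min(e, self.cds_end, pos)
            if hi > lo:
                total += hi - lo
        return total

    @property
    def coding_length(self) -> int:
        return self.coding_bases_before(self.end)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style) with an optional analysis universe."""

    sets: dict[str, frozenset[str]]
    universe: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")


@dataclass
class CopySegmentProfile:
    """Per-sample copy-number profile: non-overlapping log2-ratio segments."""

    sample_id: str
    segments: list[tuple[str, int, int, float]]

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end, _ in self.segments:
            if end <= start:
                raise ValidationError(
                    f"{self.sample_id}: segment {chrom}:{start}-{end} has end <= start"
                )
            by_chrom.setdefault(chrom, []).append((start, end))
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            for (_, e0), (s1, _) in zip(ivs, ivs[1:]):
                if s1 < e0:
                    raise ValidationError(
                        f"{self.sample_id}: overlapping segments on {chrom}"
                    )
        self.segments = sorted(self.segments, key=lambda t: (t[0], t[1]))


@dataclass(frozen=True)
class BreakpointEnd:
    """One oriented genomic end of a junction.

    Orientation ``+`` means the genomic left side of ``pos`` is retained at
    the junction; ``-`` means the right side is retained.
    """

    chrom: str
    pos: int
    orientation: str

    def __post_init__(self) -> None:
        if self.orientation not in "+-":
            raise ValidationError(f"bad orientation {self.orientation!r}")
        if self.pos < 0:
            raise ValidationError("negative breakpoint position")


@dataclass
class BreakpointPair:
    """One DNA rearrangement junction joining two oriented genomic ends."""

    id: str
    endA: BreakpointEnd
    endB: BreakpointEnd
    support_reads: int
    sample_id: str

    def __post_init__(self) -> None:
        if self.support_reads < 0:
            raise ValidationError(f"junction {self.id}: negative support")


@dataclass
class FusionCandidate:
    """One predicted chimeric transcript, in a minimal deFuse-like dialect."""

    id: str
    library_id: str
    gene5: str
    gene3: str
    end5: BreakpointEnd
    end3: BreakpointEnd
    split_reads: int
    spanning_reads: int
    is_readthrough: bool
    multimapping: bool
    repeat_fraction: float

    def __post_init__(self) -> None:
        if self.split_reads < 0 or self.spanning_reads < 0:
            raise ValidationError(f"candidate {self.id}: negative read counts")
        if not (0.0 <= self.repeat_fraction <= 1.0):
            raise ValidationError(
                f"candidate {self.id}: repeat_fraction {self.repeat_fraction} not in [0, 1]"
            )

    @property
    def total_support(self) -> int:
        return self.split_reads + self.spanning_reads


# ---------------------------------------------------------------------------
# Count matrix TSV
# ---------------------------------------------------------------------------


def read_count_matrix(path: str | Path) -> CountMatrix:
    """Read a gene x sample TSV (first column gene ids, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate gene id {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise FormatError(f"duplicate sample id {dup!r}")
    counts = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, (gene, raw) in enumerate(df[col].items()):
            try:
                v = int(raw)
            except (TypeError, ValueError):
                raise FormatError(
                    f"non-integer count {raw!r} for gene {gene!r}, sample {col!r}"
                ) from None
            if v < 0:
                raise FormatError(f"negative count for gene {gene!r}, sample {col!r}")
            counts[i, j] = v
    return CountMatrix(list(df.index), list(df.columns), counts)


def write_count_matrix(cm: CountMatrix, path: str | Path) -> None:
    cm.to_frame().to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read gene sets from GMT (name, description, then member genes)."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError(f"{path}: empty GMT file")
    for lineno, line in enumerate(lines, 1):
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
        name = fields[0]
        if name in sets:
            raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
        sets[name] = frozenset(g for g in fields[2:] if g)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, "na", *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# SEG (1-based inclusive on disk)
# ---------------------------------------------------------------------------

_SEG_COLS = ["sample_id", "chrom", "start", "end", "log2ratio"]


def read_seg(path: str | Path) -> list[CopySegmentProfile]:
    """Read copy-number segments; one profile per sample, in file order."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _SEG_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: SEG file missing columns {missing}")
    profiles: dict[str, list[tuple[str, int, int, float]]] = {}
    order: list[str] = []
    for row in df.itertuples(index=False):
        sid = str(row.sample_id)
        if sid not in profiles:
            profiles[sid] = []
            order.append(sid)
        start = int(row.start) - 1  # to 0-based half-open
        end = int(row.end)
        profiles[sid].append((str(row.chrom), start, end, float(row.log2ratio)))
    return [CopySegmentProfile(sid, profiles[sid]) for sid in order]


def write_seg(profiles: Sequence[CopySegmentProfile], path: str | Path) -> None:
    rows = []
    for p in profiles:
        for chrom, start, end, ratio in p.segments:
            rows.append((p.sample_id, chrom, start + 1, end, f"{ratio:.6f}"))
    pd.DataFrame(rows, columns=_SEG_COLS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BEDPE (0-based half-open on disk)
# ---------------------------------------------------------------------------


def read_bedpe(path: str | Path) -> list[BreakpointPair]:
    """Read junctions from 10+-column BEDPE; score = supporting read count.

    An optional 11th column carries the sample id (empty string if absent).
    """
    pairs: list[BreakpointPair] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise FormatError(f"{path}:{lineno}: BEDPE needs >=10 columns, got {len(f)}")
            if f[8] not in "+-" or f[9] not in "+-":
                raise FormatError(f"{path}:{lineno}: malformed strand {f[8]!r}/{f[9]!r}")
            try:
                support = int(f[7])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer score {f[7]!r}") from None
            sample = f[10] if len(f) > 10 else ""
            pairs.append(
                BreakpointPair(
                    id=f[6],
                    endA=BreakpointEnd(f[0], int(f[1]), f[8]),
                    endB=BreakpointEnd(f[3], int(f[4]), f[9]),
                    support_reads=support,
                    sample_id=sample,
                )
            )
    return pairs


def write_bedpe(pairs: Sequence[BreakpointPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        p.endA.chrom, p.endA.pos, p.endA.pos + 1,
                        p.endB.chrom, p.endB.pos, p.endB.pos + 1,
                        p.id, p.support_reads,
                        p.endA.orientation, p.endB.orientation,
                        p.sample_id,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Fusion candidate TSV
# ---------------------------------------------------------------------------

_FUSION_COLS = [
    "id", "library_id", "gene5", "gene3",
    "chrom5", "pos5", "strand5", "chrom3", "pos3", "strand3",
    "split_reads", "spanning_reads",
    "is_readthrough", "multimapping", "repeat_fraction",
]

# Mapping from deFuse column names to this dialect, for users converting
# native deFuse output: cluster_id->id, library_name->library_id,
# gene_name1/2->gene5/gene3, gene_chromosome1/2->chrom5/3,
# genomic_break_pos1/2->pos5/3, genomic_strand1/2->strand5/3,
# splitr_count->split_reads, span_count->spanning_reads,
# read_through->is_readthrough, multi_map->multimapping,
# repeat_proportion1*repeat_proportion2 (min 1.0)->repeat_fraction.
DEFUSE_COLUMN_MAP = {
    "cluster_id": "id",
    "library_name": "library_id",
    "gene_name1": "gene5",
    "gene_name2": "gene3",
    "gene_chromosome1": "chrom5",
    "gene_chromosome2": "chrom3",
    "genomic_break_pos1": "pos5",
    "genomic_break_pos2": "pos3",
    "genomic_strand1": "strand5",
    "genomic_strand2": "strand3",
    "splitr_count": "split_reads",
    "span_count": "spanning_reads",
    "read_through": "is_readthrough",
    "multi_map": "multimapping",
}

_BOOL = {"true": True, "false": False, "1": True, "0": False,
         "y": True, "n": False, "yes": True, "no": False}


def _parse_bool(raw: str, context: str) -> bool:
    try:
        return _BOOL[str(raw).strip().lower()]
    except KeyError:
        raise FormatError(f"{context}: cannot parse boolean {raw!r}") from None


def read_fusion_candidates(path: str | Path) -> list[FusionCandidate]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _FUSION_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: fusion table missing columns {missing}")
    out: list[FusionCandidate] = []
    for row in df.itertuples(index=False):
        cid = str(row.id)
        try:
            out.append(
                FusionCandidate(
                    id=cid,
                    library_id=str(row.library_id),
                    gene5=str(row.gene5),
                    gene3=str(row.gene3),
                    end5=BreakpointEnd(str(row.chrom5), int(row.pos5), str(row.strand5)),
                    end3=BreakpointEnd(str(row.chrom3), int(row.pos3), str(row.strand3)),
                    split_reads=int(row.split_reads),
                    spanning_reads=int(row.spanning_reads),
                    is_readthrough=_parse_bool(row.is_readthrough, cid),
                    multimapping=_parse_bool(row.multimapping, cid),
                    repeat_fraction=float(row.repeat_fraction),
                )
            )
        except ValidationError as err:
            raise FormatError(f"{path}: candidate {cid}: {err}") from None
    return out


def write_fusion_candidates(cands: Sequence[FusionCandidate], path: str | Path) -> None:
    rows = []
    for c in cands:
        rows.append(
            (
                c.id, c.library_id, c.gene5, c.gene3,
                c.end5.chrom, c.end5.pos, c.end5.orientation,
                c.end3.chrom, c.end3.pos, c.end3.orientation,
                c.split_reads, c.spanning_reads,
                str(c.is_readthrough).lower(), str(c.multimapping).lower(),
                f"{c.repeat_fraction:.6f}",
            )
        )
    pd.DataFrame(rows, columns=_FUSION_COLS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GTF-like gene models (1-based inclusive on disk)
# ---------------------------------------------------------------------------

_GENE_ID_RE = re.compile(r'gene_id "([^"]+)"')


def read_gene_models(path: str | Path) -> dict[str, GeneModel]:
    """Read exon/CDS lines of a GTF-like file into GeneModel objects."""
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise FormatError(f"{path}:{lineno}: GTF line needs 9 columns")
            chrom, _, feature, start, end, _, strand, _, attrs = f[:9]
            m = _GENE_ID_RE.search(attrs)
            if m is None:
                raise FormatError(f"{path}:{lineno}: no gene_id attribute")
            gid = m.group(1)
            iv = (int(start) - 1, int(end))  # to 0-based half-open
            if gid in meta and meta[gid] != (chrom, strand):
                raise FormatError(f"{path}:{lineno}: gene {gid} on multiple chroms/strands")
            meta[gid] = (chrom, strand)
            if feature == "exon":
                exons.setdefault(gid, []).append(iv)
            elif feature == "CDS":
                cds.setdefault(gid, []).append(iv)
    models: dict[str, GeneModel] = {}
    for gid, ex in exons.items():
        chrom, strand = meta[gid]
        cstart = cend = None
        if gid in cds:
            cstart = min(s for s, _ in cds[gid])
            cend = max(e for _, e in cds[gid])
        models[gid] = GeneModel(gid, chrom, strand, ex, cstart, cend)
    return models


def write_gene_models(models: Mapping[str, GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid in models:
            g = models[gid]
            attrs = f'gene_id "{gid}";'
            for s, e in g.exons:
                fh.write(f"{g.chrom}\thtx\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n")
            if g.has_cds:
                for s, e in g.exons:
                    lo, hi = max(s, g.cds_start), min(e, g.cds_end)
                    if hi > lo:
                        fh.write(
                            f"{g.chrom}\thtx\tCDS\t{lo + 1}\t{hi}\t.\t{g.strand}\t.\t{attrs}\n"
                        )
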