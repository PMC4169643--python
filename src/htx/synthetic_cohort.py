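"""Synthetic cohort generator with planted ground truth.

Emits every input the pipeline consumes — a negative-binomial count matrix
with planted outlier genes, per-library background noise, a labeled
fusion-candidate table with corroborating DNA junctions, chromoplexy-like
breakpoint chains, and copy-number profiles carrying nested/serial tandem
duplications — together with a truth table, so every downstream stage can
be validated without any external data. All randomness flows from the
config seed; identical configs produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .formats_io import (
    BreakpointEnd,
    BreakpointPair,
    CopySegmentProfile,
    CountMatrix,
    FusionCandidate,
    GeneModel,
    ValidationError,
)
from .outlier_expression import NoiseEstimate

__all__ = [
    "OutlierSpec",
    "NoiseSpec",
    "FusionSpec",
    "ChainSpec",
    "TdSpec",
    "SimConfig",
    "TruthTable",
    "simulate_counts",
    "simulate_noise",
    "simulate_fusion_candidates",
    "simulate_complex_chain",
    "simulate_tandem_dup_genome",
    "make_gene_models",
]

# Toy reference: 22 autosomes of 100 Mb each.
CHROMS = [f"chr{i}" for i in range(1, 23)]
CHROM_LEN = 100_000_000

ETS_GENES = ("ERG", "ETV1", "ETV4", "ETV5", "FLI1")


@dataclass
class OutlierSpec:
    """Planted outlier genes: multiplicative fold change in carrier samples.

    Planted genes are drawn from genes whose expected depth clears
    ``min_expected_depth`` — the outlier definition downstream only admits
    genes above 10x after noise subtraction, so truth planted below that
    floor would be undetectable by construction rather than by failure.
    """

    n_outlier_genes: int = 300
    fold_change: float = 16.0
    n_carrier_samples: int = 2
    min_expected_depth: float = 20.0


@dataclass
class NoiseSpec:
    """Per-library mean intergenic/intronic coverage (background noise)."""

    mean_depth: float = 0.5
    sd: float = 0.0  # 0 => deterministic


@dataclass
class FusionSpec:
    """Class sizes for the candidate table; each artifact class violates
    exactly one primary filter criterion."""

    n_true: int = 20
    n_ets_true_libraries: int = 15  # one recurrent ETS fusion in this many libraries
    n_readthrough: int = 10
    n_recurrent_artifact_pairs: int = 3   # each planted in 4 libraries
    n_multimap: int = 5
    n_repeat: int = 5
    n_low_support: int = 10


@dataclass
class ChainSpec:
    n_chains: int = 3
    breakpoints_per_chain: int = 6


@dataclass
class TdSpec:
    """Tandem-duplication genome: mostly isolated clonal events plus one
    nested (serial) locus and a handful of sub-clonal junctions."""

    n_duplications: int = 241       # total, including the nested locus
    n_nested: int = 3               # concentric duplications at one locus
    nested_copies: tuple[float, ...] = (1.0, 1.0, 3.0)  # outer -> inner
    n_subclonal: int = 5
    subclonal_fraction: float = 0.4
    clonal_support: int = 50        # junction reads per clonal copy
    log2_noise_sd: float = 0.02     # segment-level aCGH noise
    n_decoy_junctions: int = 20     # deletion/inversion junctions, never TDs
    min_length: int = 50_000
    max_length: int = 2_000_000


@dataclass
class SimConfig:
    n_samples: int = 31
    n_genes: int = 2000
    nb_mean_log_range: tuple[float, float] = (0.5, 3.5)  # log10 of mean counts
    nb_dispersion: float = 0.2
    read_length: int = 100
    outlier_spec: OutlierSpec = field(default_factory=OutlierSpec)
    noise_spec: NoiseSpec = field(default_factory=NoiseSpec)
    fusion_spec: FusionSpec = field(default_factory=FusionSpec)
    chain_spec: ChainSpec = field(default_factory=ChainSpec)
    td_spec: TdSpec = field(default_factory=TdSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outlier_spec.fold_change <= 1:
            raise ValidationError("fold_change must be > 1")
        if self.outlier_spec.n_carrier_samples >= self.n_samples:
            raise ValidationError("n_carrier_samples must be < n_samples")
        if self.noise_spec.mean_depth < 0 or self.noise_spec.sd < 0:
            raise ValidationError("noise spec values must be >= 0")
        if self.td_spec.subclonal_fraction <= 0:
            raise ValidationError("sub-clonal fraction must be positive")
        if any(c <= 0 for c in self.td_spec.nested_copies):
            raise ValidationError("nested duplication copies must be positive")

    @property
    def sample_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_samples)]

    @classmethod
    def from_dict(cls, data: dict) -> "SimConfig":
        """Build a config from a plain (JSON-style) dict with nested specs."""
        nested = {
            "outlier_spec": OutlierSpec,
            "noise_spec": NoiseSpec,
            "fusion_spec": FusionSpec,
            "chain_spec": ChainSpec,
            "td_spec": TdSpec,
        }
        kwargs = dict(data)
        for key, typ in nested.items():
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = typ(**kwargs[key])
        if "nb_mean_log_range" in kwargs:
            kwargs["nb_mean_log_range"] = tuple(kwargs["nb_mean_log_range"])
        return cls(**kwargs)


@dataclass
class TruthTable:
    """Planted ground truth for every emitted entity."""

    outliers: list[tuple[str, str, str]] = field(default_factory=list)
    fusion_labels: dict[str, str] = field(default_factory=dict)
    chain_members: dict[str, list[str]] = field(default_factory=dict)
    chain_expressed_fusion: dict[str, str] = field(default_factory=dict)
    tandem_duplications: list[dict] = field(default_factory=list)


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    # Independent substream per stage so changing one spec does not
    # perturb the others.
    return np.random.default_rng([config.seed, stage])


# ---------------------------------------------------------------------------
# Counts, gene models, noise
# ---------------------------------------------------------------------------


def make_gene_models(config: SimConfig) -> dict[str, GeneModel]:
    """Deterministic single-exon models for the count-matrix genes,
    tiled across the toy reference 1 Mb apart."""
    rng = _rng(config, 0)
    lengths = np.exp(
        rng.uniform(np.log(500), np.log(5000), size=config.n_genes)
    ).astype(int)
    models: dict[str, GeneModel] = {}
    per_chrom = CHROM_LEN // 1_000_000 - 2
    for i in range(config.n_genes):
        gid = f"G{i + 1:05d}"
        chrom = CHROMS[(i // per_chrom) % len(CHROMS)]
        start = 1_000_000 * (i % per_chrom) + 10_000
        models[gid] = GeneModel(gid, chrom, "+", [(start, start + int(lengths[i]))])
    return models


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, TruthTable, dict[str, GeneModel]]:
    """NB(mean_g * s_j, dispersion) counts with planted multiplicative outliers.

    Library-size factors s_j are drawn log-uniform on [0.5, 2]; outlier
    genes are multiplied by ``fold_change`` in their carrier samples, with
    the carrier counts re-drawn at the inflated mean.
    """
    models = make_gene_models(config)
    rng = _rng(config, 1)
    lo, hi = config.nb_mean_log_range
    means = 10.0 ** rng.uniform(lo, hi, size=config.n_genes)
    size_factors = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=config.n_samples))
    mu = means[:, None] * size_factors[None, :]
    counts = _nb_draw(rng, mu, config.nb_dispersion)

    truth = TruthTable()
    spec = config.outlier_spec
    gene_ids = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    if spec.n_outlier_genes > 0:
        lengths = np.array([models[g].gene_length for g in gene_ids], dtype=float)
        expected_depth = means * config.read_length / lengths
        eligible = np.flatnonzero(expected_depth >= spec.min_expected_depth)
        if eligible.size < spec.n_outlier_genes:
            raise ValidationError(
                f"only {eligible.size} genes clear the planted-depth floor; "
                f"cannot plant {spec.n_outlier_genes} outliers"
            )
        chosen = rng.choice(eligible, size=spec.n_outlier_genes, replace=False)
        for gi in chosen:
            carriers = rng.choice(config.n_samples, size=spec.n_carrier_samples, replace=False)
            for j in carriers:
                mu_out = means[gi] * spec.fold_change * size_factors[j]
                counts[gi, j] = _nb_draw(rng, np.array([mu_out]), config.nb_dispersion)[0]
                truth.outliers.append((gene_ids[gi], config.sample_ids[j], "up"))
    cm = CountMatrix(gene_ids, config.sample_ids, counts.astype(np.int64))
    return cm, truth, models


def simulate_noise(config: SimConfig) -> NoiseEstimate:
    """Per-sample mean background depth, deterministic when sd == 0."""
    spec = config.noise_spec
    if spec.sd == 0:
        depths = np.full(config.n_samples, spec.mean_depth)
    else:
        rng = _rng(config, 2)
        depths = np.clip(
            rng.normal(spec.mean_depth, spec.sd, size=config.n_samples), 0.0, None
        )
    return NoiseEstimate(config.sample_ids, depths)


# ---------------------------------------------------------------------------
# Fusion candidates
# ---------------------------------------------------------------------------


def _random_locus(rng: np.random.Generator) -> tuple[str, int]:
    chrom = CHROMS[int(rng.integers(len(CHROMS)))]
    pos = int(rng.integers(5_000_000, CHROM_LEN - 5_000_000))
    return chrom, pos


def simulate_fusion_candidates(
    config: SimConfig,
) -> tuple[list[FusionCandidate], list[BreakpointPair], TruthTable]:
    """Candidate table in which each artifact class violates exactly one
    primary criterion; true fusions carry a corroborating DNA junction,
    artifacts do not. One ETS fusion recurs across many libraries (true
    despite recurrence, exercising the exemption)."""
    rng = _rng(config, 3)
    spec = config.fusion_spec
    samples = config.sample_ids
    truth = TruthTable()
    candidates: list[FusionCandidate] = []
    junctions: list[BreakpointPair] = []
    counter = 0
    gene_counter = 0

    def next_gene() -> str:
        nonlocal gene_counter
        gene_counter += 1
        return f"FG{gene_counter:04d}"

    def emit(label: str, gene5: str, gene3: str, library: str, *,
             split: int, spanning: int, readthrough: bool = False,
             multimap: bool = False, repeat: float = 0.0,
             loci: tuple | None = None, with_junction: bool = False) -> None:
        nonlocal counter
        counter += 1
        cid = f"fc{counter:04d}"
        if loci is None:
            loci = (_random_locus(rng), _random_locus(rng))
        (c5, p5), (c3, p3) = loci
        end5 = BreakpointEnd(c5, p5, "+")
        end3 = BreakpointEnd(c3, p3, "-")
        candidates.append(
            FusionCandidate(
                id=cid, library_id=library, gene5=gene5, gene3=gene3,
                end5=end5, end3=end3, split_reads=split, spanning_reads=spanning,
                is_readthrough=readthrough, multimapping=multimap,
                repeat_fraction=repeat,
            )
        )
        truth.fusion_labels[cid] = label
        if with_junction:
            junctions.append(
                BreakpointPair(
                    id=f"j_{cid}", endA=end5, endB=end3,
                    support_reads=int(rng.integers(10, 50)), sample_id=library,
                )
            )

    def support() -> tuple[int, int]:
        return int(rng.integers(3, 20)), int(rng.integers(3, 20))

    for _ in range(spec.n_true):
        s, sp = support()
        emit("true", next_gene(), next_gene(),
             samples[int(rng.integers(len(samples)))],
             split=s, spanning=sp, with_junction=True)

    if spec.n_ets_true_libraries > 0:
        ets_loci = (_random_locus(rng), _random_locus(rng))
        libs = rng.choice(len(samples), size=min(spec.n_ets_true_libraries, len(samples)),
                         replace=False)
        for j in sorted(libs):
            s, sp = support()
            emit("true_ets", "TMPRSS2", "ERG", samples[int(j)],
                 split=s, spanning=sp, loci=ets_loci, with_junction=True)

    for _ in range(spec.n_readthrough):
        s, sp = support()
        # Readthroughs join adjacent genes on one chromosome.
        chrom, pos = _random_locus(rng)
        emit("readthrough", next_gene(), next_gene(),
             samples[int(rng.integers(len(samples)))],
             split=s, spanning=sp, readthrough=True,
             loci=((chrom, pos), (chrom, pos + 30_000)))

    for _ in range(spec.n_recurrent_artifact_pairs):
        g5, g3 = next_gene(), next_gene()
        loci = (_random_locus(rng), _random_locus(rng))
        libs = rng.choice(len(samples), size=4, replace=False)
        for j in sorted(libs):
            s, sp = support()
            emit("recurrent_artifact", g5, g3, samples[int(j)],
                 split=s, spanning=sp, loci=loci)

    for _ in range(spec.n_multimap):
        s, sp = support()
        emit("multimap_artifact", next_gene(), next_gene(),
             samples[int(rng.integers(len(samples)))],
             split=s, spanning=sp, multimap=True)

    for _ in range(spec.n_repeat):
        s, sp = support()
        emit("repeat_artifact", next_gene(), next_gene(),
             samples[int(rng.integers(len(samples)))],
             split=s, spanning=sp, repeat=1.0)

    for _ in range(spec.n_low_support):
        total = int(rng.integers(1, 6))  # boundary of the >5 reads rule
        s = int(rng.integers(0, total + 1))
        emit("low_support", next_gene(), next_gene(),
             samples[int(rng.integers(len(samples)))],
             split=s, spanning=total - s)

    return candidates, junctions, truth


# ---------------------------------------------------------------------------
# Complex (chromoplexy-like) chains
# ---------------------------------------------------------------------------


def simulate_complex_chain(
    k_breakpoints: int,
    genes: Sequence[GeneModel],
    sample_id: str,
    rng: np.random.Generator,
    id_prefix: str = "chain",
) -> tuple[list[BreakpointPair], Optional[FusionCandidate]]:
    """One closed chain of ``k`` junctions threading ``k`` gene loci.

    Junction i joins a breakpoint inside gene i to one inside gene i+1
    (cyclically), so consecutive junction ends at each locus fall within a
    few kb of each other — the topology of a chromoplexy chain. With k=2
    the construction degenerates to a simple reciprocal event. Exactly one
    designated junction is also returned as an expressed fusion candidate
    (chromoplexy chains typically express very few of their junctions).
    """
    if k_breakpoints < 2:
        raise ValidationError("a chain needs at least 2 breakpoints")
    if len(genes) != k_breakpoints:
        raise ValidationError("need exactly one gene locus per breakpoint")
    # Two nearby breakpoint positions inside each gene, one for each of the
    # two junctions touching that locus.
    pos_pairs = []
    for g in genes:
        base = int(rng.integers(g.start, max(g.start + 1, g.end - 2_000)))
        pos_pairs.append((base, base + int(rng.integers(100, 2_000))))
    junctions: list[BreakpointPair] = []
    for i in range(k_breakpoints):
        gi, gj = genes[i], genes[(i + 1) % k_breakpoints]
        endA = BreakpointEnd(gi.chrom, pos_pairs[i][1], "+")
        endB = BreakpointEnd(gj.chrom, pos_pairs[(i + 1) % k_breakpoints][0], "-")
        junctions.append(
            BreakpointPair(
                id=f"{id_prefix}_j{i + 1}", endA=endA, endB=endB,
                support_reads=int(rng.integers(8, 40)), sample_id=sample_id,
            )
        )
    expressed = junctions[0]
    fusion = FusionCandidate(
        id=f"{id_prefix}_fusion",
        library_id=sample_id,
        gene5=genes[0].gene_id,
        gene3=genes[1 % k_breakpoints].gene_id,
        end5=expressed.endA,
        end3=expressed.endB,
        split_reads=int(rng.integers(4, 15)),
        spanning_reads=int(rng.integers(4, 15)),
        is_readthrough=False,
        multimapping=False,
        repeat_fraction=0.0,
    )
    return junctions, fusion


# ---------------------------------------------------------------------------
# Tandem-duplication genome
# ---------------------------------------------------------------------------


def _dup_junction(jid: str, chrom: str, start: int, end: int, support: int,
                  sample_id: str) -> BreakpointPair:
    # Head-to-tail convention: + end at the gain start, - end at the gain end.
    return BreakpointPair(
        id=jid,
        endA=BreakpointEnd(chrom, end, "-"),
        endB=BreakpointEnd(chrom, start, "+"),
        support_reads=support,
        sample_id=sample_id,
    )


def simulate_tandem_dup_genome(
    config: SimConfig,
    sample_id: str = "T4",
    n_duplications: Optional[int] = None,
) -> tuple[CopySegmentProfile, list[BreakpointPair], TruthTable]:
    """Genome of a tandem-duplicator tumor.

    Isolated clonal duplications (integer extra copies), one nested locus
    of concentric serial duplications whose inner junction support is
    multiplied by the outer copies (the breakpoint itself duplicated), and
    sub-clonal duplications at a fixed cell fraction whose coverage step
    falls below the focal-gain threshold — detectable only via junction
    support. Segment log2 ratios carry small Gaussian noise; decoy
    deletion/inversion junctions are added as matcher negatives.
    """
    rng = _rng(config, 4)
    spec = config.td_spec
    total = spec.n_duplications if n_duplications is None else n_duplications
    n_nested = spec.n_nested if total >= spec.n_nested + 1 else 0
    n_isolated = total - n_nested
    n_sub = min(spec.n_subclonal, n_isolated)
    truth = TruthTable()

    # Non-overlapping isolated intervals, tiled with jitter.
    events: list[dict] = []  # chrom,start,end,copies,subclonal,parent
    per_chrom = max(1, int(np.ceil(n_isolated / len(CHROMS))))
    slot = (CHROM_LEN - 10_000_000) // per_chrom
    placed = 0
    for chrom in CHROMS:
        for s in range(per_chrom):
            if placed >= n_isolated:
                break
            length = int(rng.integers(spec.min_length, spec.max_length))
            length = min(length, slot - 200_000)
            start = 5_000_000 + s * slot + int(rng.integers(0, max(1, slot - length - 100_000)))
            copies = float(rng.choice([1.0, 1.0, 1.0, 2.0, 3.0]))
            events.append(
                dict(chrom=chrom, start=start, end=start + length, copies=copies,
                     subclonal=False, parent=None)
            )
            placed += 1
    # Mark the last n_sub isolated events sub-clonal.
    for ev in events[-n_sub:] if n_sub else []:
        ev["copies"] = spec.subclonal_fraction
        ev["subclonal"] = True

    # Nested locus on the last chromosome, in reserved tail space.
    nested: list[dict] = []
    if n_nested:
        chrom = CHROMS[-1]
        outer_len = 3_000_000
        outer_start = CHROM_LEN - 4_500_000
        bounds = (outer_start, outer_start + outer_len)
        for level in range(n_nested):
            shrink = level * outer_len // (2 * n_nested)
            s, e = bounds[0] + shrink, bounds[1] - shrink
            nested.append(
                dict(chrom=chrom, start=s, end=e,
                     copies=float(spec.nested_copies[level % len(spec.nested_copies)]),
                     subclonal=False, parent=None)
            )
        for level in range(1, n_nested):
            nested[level]["parent"] = level - 1

    all_events = events + nested

    # Piecewise-constant copy profile via boundary sweep per chromosome.
    segments: list[tuple[str, int, int, float]] = []
    for chrom in CHROMS:
        evs = [e for e in all_events if e["chrom"] == chrom]
        cuts = sorted({0, CHROM_LEN} | {e["start"] for e in evs} | {e["end"] for e in evs})
        for a, b in zip(cuts, cuts[1:]):
            extra = sum(e["copies"] for e in evs if e["start"] <= a and b <= e["end"])
            log2 = float(np.log2((2.0 + extra) / 2.0))
            log2 += float(rng.normal(0.0, spec.log2_noise_sd))
            segments.append((chrom, a, b, log2))
    profile = CopySegmentProfile(sample_id, segments)

    # Junctions: one head-to-tail junction per duplication.
    junctions: list[BreakpointPair] = []
    for i, ev in enumerate(all_events):
        jid = f"tdj{i + 1:04d}"
        parent_copies = 0.0
        j = ev
        while j["parent"] is not None:
            j = nested[j["parent"]]
            parent_copies += j["copies"]
        mult = 1.0 + parent_copies  # inner breakpoints duplicated by outer events
        support = max(1, int(round(spec.clonal_support * ev["copies"] * mult)))
        junctions.append(
            _dup_junction(jid, ev["chrom"], ev["start"], ev["end"], support, sample_id)
        )
        truth.tandem_duplications.append(
            dict(
                junction_id=jid, chrom=ev["chrom"], start=ev["start"], end=ev["end"],
                copies=ev["copies"], subclonal=ev["subclonal"],
                parent_junction_id=(
                    f"tdj{len(events) + ev['parent'] + 1:04d}"
                    if ev["parent"] is not None else None
                ),
            )
        )

    # Decoy junctions with deletion / inversion orientations.
    for d in range(spec.n_decoy_junctions):
        chrom = CHROMS[int(rng.integers(len(CHROMS)))]
        start = int(rng.integers(1_000_000, CHROM_LEN - 2_000_000))
        end = start + int(rng.integers(spec.min_length, spec.max_length))
        # Duplication junctions are (+ at start, - at end); deletions are the
        # mirror image and inversions have equal orientations.
        kind = ("+", "-") if d % 2 == 0 else ("+", "+")  # (endA at end, endB at start)
        junctions.append(
            BreakpointPair(
                id=f"decoy{d + 1:03d}",
                endA=BreakpointEnd(chrom, end, kind[0]),
                endB=BreakpointEnd(chrom, start, kind[1]),
                support_reads=int(rng.integers(5, 40)),
                sample_id=sample_id,
            )
        )

    return profile, junctions, truth


def simulate_flat_profile(
    config: SimConfig, sample_id: str, n_gains: int = 5
) -> CopySegmentProfile:
    """Control genome: near-diploid with a handful of focal gains."""
    rng = np.random.default_rng([config.seed, 5, abs(hash(sample_id)) % (2**31)])
    segments: list[tuple[str, int, int, float]] = []
    gain_chroms = rng.choice(len(CHROMS), size=n_gains, replace=False)
    for ci, chrom in enumerate(CHROMS):
        if ci in gain_chroms:
            start = int(rng.integers(10_000_000, 80_000_000))
            end = start + int(rng.integers(200_000, 1_500_000))
            segments.append((chrom, 0, start, float(rng.normal(0, 0.02))))
            segments.append((chrom, start, end, float(np.log2(1.5) + rng.normal(0, 0.02))))
            segments.append((chrom, end, CHROM_LEN, float(rng.normal(0, 0.02))))
        else:
            segments.append((chrom, 0, CHROM_LEN, float(rng.normal(0, 0.02))))
    return CopySegmentProfile(sample_id, segments)
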