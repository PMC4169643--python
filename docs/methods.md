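# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of the pipeline. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Normalization and depth

Size factors are median-of-ratios: the pseudo-reference for gene i is the
geometric mean of its counts across samples, and s_j is the median over
genes of k_ij divided by the reference. Genes with any zero count are
excluded from the median (their geometric mean vanishes); if no gene has
all-positive counts the factors are undefined and the package raises
rather than falling back to an ad-hoc reference. Sequence depth in
×-coverage is (k_ij / s_j) · read_length / gene_length, with gene length
the sum of exon lengths. Depth, not raw counts, is what the 10× rules
operate on.

## Background noise

Per-library background noise — the mean coverage of intergenic and
intronic regions, which should be largely absent from pure RNA-seq — is a
single scalar per library, subtracted uniformly from every gene's depth
and clamped at zero. A scalar is used because the noise estimate is
itself a genome-wide average; gene-specific contamination (e.g. intronic
read-through at specific loci) is not modeled.

## Generalized ESD outlier calling

The test is Rosner's many-outlier procedure: at step i the extreme
studentized deviate R_i is computed on the remaining data and the extreme
point removed; the critical value λ_i uses the t-quantile at
p = 1 − α/(2(n − i + 1)) with n − i − 1 degrees of freedom; the declared
outlier count is the largest i with R_i > λ_i (all points removed up to
that step are declared, the standard convention, even if an intermediate
step fell below its critical value). Ties in the deviate are broken
toward the lower sample index; a zero standard deviation stops the
recursion (constant data has no outliers). r defaults to 15 and is capped
at half the cohort size. α defaults to 0.05 and is configurable.

The test runs on log2(depth + 1) after noise subtraction. ESD assumes
approximate normality; RNA-seq depth is approximately log-normal across
samples, so the log scale is the defensible choice, and a flag allows
running on raw depth instead.

Calls are gated by three rules: an up-regulated outlier must itself
exceed 10× noise-corrected depth; a down-regulated outlier requires the
*non-outlier* mean to exceed 10× (otherwise "low against low" is noise);
and a gene flagged in more than floor(n/3) libraries is not an outlier at
the cohort level and is dropped entirely. The one-third denominator is
all libraries in the run.

### Type-I behavior (measured, not assumed)

Two facts about the procedure's calibration, both computed by the
acceptance machinery:

1. Even on exactly normal data the many-outlier procedure's family-wise
   rate of declaring ≥ 1 outlier exceeds α: each step's λ_i is calibrated
   marginally, and the declaration rule is a union over r = 15 steps.
   At n = 31 the measured rate is ≈ 0.057 at α = 0.05 (step 1 alone is
   ≈ 0.05).
2. On negative-binomial cohorts the rate is substantially higher
   (≈ 0.08–0.09 on the pipeline's log-depth scale at dispersion 0.2, and
   0.13–0.16 on log raw counts): for NB counts with gamma shape
   1/dispersion = 5, the log transform leaves a left-skewed distribution,
   and the two-sided deviate flags the heavy lower tail. This is a
   property of running a normal-theory outlier test on over-dispersed
   count data, and it is why the planted-recovery evaluation scores the
   planted (up) direction: spurious calls concentrate in the down
   direction, where no truth is planted, while up-direction precision is
   ≈ 0.99.

Consequence: the per-gene probability of any declared outlier on a null
NB cohort is *not* α, and the test suite asserts the nominal property
honestly (it fails at these study conditions, by the measured margins
above). Users needing strict type-I control at α should either lower α
or pre-transform toward normality (e.g. rank-based); both are outside
the reference procedure reproduced here.

## Enrichment

Over-representation uses the exact hypergeometric upper tail; the
universe defaults to all genes in the count matrix (the most conservative
defensible choice); the BH family is the sets tested for one sample
(scores are displayed per sample). Both up- and down-outliers enter the
query by default. The pathway score is −log10(BH-adjusted p) and the
display rule is score > 1 strictly, so an adjusted p of exactly 0.1 is
hidden. The knowledge base is user-supplied GMT: the statistical
construct is reproduced, not any proprietary pathway content.

## Fusion filter cascade

Criteria, in order: (1) not a readthrough; (2) predicted in at most 2
distinct libraries per ordered (gene5, gene3) pair — waived for
candidates with an ETS-family partner (default list ERG, ETV1, ETV4,
ETV5, FLI1, configurable), because ETS fusions genuinely recur in about
half of prostate tumors and the criterion exists to remove recurrent
artifacts; the exemption never rescues a candidate failing any other
criterion; (3) unambiguous mapping on both sides, consumed as an
upstream boolean since alignment is out of scope; (4) "entirely within
repeats" read strictly as repeat_fraction = 1.0; (5) split + spanning
reads > 5, a strict inequality (5 reads fail, 6 pass).

Secondary prioritization flags (any one suffices): a genomic breakpoint
within 100 kb of a copy-number segment boundary with |Δlog2| ≥ 0.3;
mean exon depth differing ≥ 2-fold between the retained and lost side of
the junction within either partner; an up-outlier call for the 3′ gene in
the same library. No thresholds for these are given by the reference
procedure; the defaults are configurable and flagged undetermined (never
fatal) when their inputs are missing.

DNA corroboration requires library genome coverage strictly > 5×; a
junction matches when both ends are within 10 bp (configurable) with
equal orientations, in either end order.

## Complex rearrangements

Junction ends are nodes; edges join the two ends of each junction and
ends of different junctions within 1 Mb on the reference. Connected
components with more than two junctions are events. The linking window is
an approximation to chain discovery from assembly evidence: chromoplexy
chains revisit loci, so consecutive junction ends co-locate within a few
kb, while 1 Mb stays well below the spacing of independent events in the
synthetic genomes. The breakpoint count of an event is its junction
count. Gene effects: activating if the gene is the 3′ partner of an
in-frame expressed fusion in the event or carries an up-outlier call in
that sample; disrupted if any member breakpoint falls inside its CDS
without activating evidence; neutral otherwise.

## Reading frame

A junction is in frame iff both breakpoints lie within annotated CDS and
the coding length retained from the 5′ partner is congruent mod 3 to the
CDS phase at the 3′ junction. Strand is handled by counting coding bases
in transcription order; the computation is invariant to translating a
whole gene model along the chromosome. Candidates with a partner lacking
CDS are undetermined; a breakpoint outside the gene span is a caller
error, not a status.

## Tandem duplications

Orientation convention (internal, mirrored by the simulator): a
duplication junction has its `+` end at the gain start and `-` end at the
gain end; deletions are the mirror image and inversions have equal
orientations, so only duplication-type junctions can ever match.

Matching: a gain matches a junction directly when both boundaries agree
within 10 kb. At nested/serial loci the profile is a staircase of
non-overlapping segments, so a junction may instead align its start to
one gain segment's start and its end to a *different* segment's end with
only elevated segments between; the duplication's representative log2
ratio is then the minimum elevated ratio inside its span — the region
covered by the fewest co-occurring duplications. Copies follow
c = 2·2^log2 − 2 minus the summed copies of containing duplications
(estimated outermost first); for concentric nesting this reproduces the
additive copy model exactly, and it also handles partially overlapping
serial pairs. The nested_parent link points to the smallest strict
container, so nesting forms a forest. A head-to-tail junction with no
coverage step (sub-clonal events diluted below the 0.3 gain threshold:
a 0.4-fraction duplication gives log2(2.4/2) ≈ 0.26) becomes a
junction-only record whose copies are support / clonal reference.

Estimates below 1 are flagged sub-clonal. For a clonal single-copy
duplication the coverage estimate hovers at exactly 1.0, so under any
segment noise the strict < 1 rule is an unavoidable coin flip for that
class; the flag is informative for junction-only events and for estimates
well away from 1.

Genotype: ≥ 50 matched duplications ("tens to hundreds") calls the
duplicator genotype. Cohort screening from copy number alone counts focal
gains and labels qualifying samples "putative" — categorical detection of
tandem duplications is not possible without junction evidence — upgraded
to "confirmed" when supplied junctions yield enough matches.

## Synthetic cohort

The generator emulates the study conditions: 31 libraries; 2,000 genes
with log10 mean counts uniform on [0.5, 3.5] and NB dispersion 0.2
(spanning lowly to highly expressed bulk RNA-seq genes); library size
factors log-uniform on [0.5, 2]; 300 outlier genes at fold 16 with 2
carriers each, planted multiplicatively with carrier counts re-drawn at
the inflated mean; background noise 0.5× per library (deterministic by
default, optionally stochastic). Planted outlier genes are drawn from
genes whose expected depth clears 20×, since the outlier definition
itself only admits genes above 10× — truth planted below the
detectability floor would measure the floor, not the method. Fusion
classes each violate exactly one criterion; one ETS fusion recurs across
15 libraries; true fusions carry corroborating junctions, artifacts do
not. Chains are closed k-junction cycles through k gene loci with one
expressed fusion each. The duplicator genome plants 241 duplications
(mostly single-copy, some 2–3 copies) with one 3-level concentric locus
whose inner junction support is multiplied by the outer copies (the
breakpoint itself duplicated), five 0.4-fraction sub-clonal events, and
20 deletion/inversion decoy junctions; segment log2 ratios carry Gaussian
noise with sd 0.02, the scale of an aCGH segment mean over ~100 probes;
junction support is clonal_support (50) × copies, deterministic.

What the generator does not emulate: read-level error, GC / length
biases, correlated gene programs, impure tumor samples, segmentation
artifacts in copy number, and fusion breakpoint sequence content. Passing
tests therefore demonstrate the correctness and calibration of the
procedures under their stated statistical assumptions, not robustness to
every artifact of real libraries.

## Problem sizes and determinism

The acceptance script runs the cohort at full study scale (31 libraries ×
2,000–5,000 genes, 241 duplications, 500 oracle vectors); the unit suite
uses scaled-down cohorts of a few hundred genes. One seed governs all
randomness: generator substreams are spawned per stage so changing one
spec leaves the others' draws unchanged, and identical configs produce
byte-identical outputs (sorted JSON keys, fixed float formats).
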