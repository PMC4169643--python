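# htx

Outlier expression, fusion-transcript filtering, complex-rearrangement
reconstruction and tandem-duplication genotyping for tumor transcriptome
cohorts — the computational core of an integrated RNA-seq / whole-genome /
copy-number analysis of high-risk prostate tumors, re-implemented as a
tested, reusable pipeline driven by a synthetic-cohort generator so every
stage is verifiable without access to patient data.

## What it computes

**Per-sample outlier expression.** Raw counts k<sub>ij</sub> are normalized
by median-of-ratios size factors
s<sub>j</sub> = median<sub>i</sub> k<sub>ij</sub> / (∏<sub>v</sub> k<sub>iv</sub>)<sup>1/m</sup>
and converted to sequence depth (k<sub>ij</sub>/s<sub>j</sub> ·
read_length / gene_length). After subtracting each library's background
noise (mean intergenic/intronic coverage), the generalized extreme
studentized deviate (ESD) test is run per gene across samples on
log₂(depth + 1): at step i the statistic
R<sub>i</sub> = max<sub>k</sub> |x<sub>k</sub> − x̄| / s is compared with

&nbsp;&nbsp;λ<sub>i</sub> = (n − i) · t<sub>p, n−i−1</sub> / √((n − i − 1 + t²)(n − i + 1)),&nbsp;&nbsp;p = 1 − α / (2(n − i + 1)),

for up to r = 15 outliers (capped at half the cohort). Up-calls require
noise-corrected depth > 10×, down-calls require the non-outlier mean
> 10×, and genes flagged in more than a third of the cohort are dropped.

**Pathway enrichment.** Each sample's outlier genes are tested against a
GMT collection with the hypergeometric tail P(X ≥ k), BH-adjusted per
sample; the pathway score is −log₁₀(adjusted p) and results with score
> 1 (adjusted p < 0.1) are displayed.

**Fusion filtering.** Chimeric-RNA candidates pass five criteria: (1)
genome rearrangement, not readthrough; (2) predicted in ≤ 2 libraries
(waived for ETS-family fusions, which recur genuinely); (3) unambiguous
mapping on both sides; (4) not entirely within repeats; (5) > 5 split +
spanning reads. Retained candidates are prioritized by copy-number-edge
proximity, differential exon expression across the junction and 3′-gene
outlier expression, and corroborated against DNA junctions in libraries
with > 5× genome coverage. Complex rearrangements (chromoplexy-like
chains) are connected components of a breakpoint graph with > 2
junctions; member genes are classified activating / disrupted / neutral
and junction reading frames assessed from CDS phase arithmetic.

**Tandem duplications.** Focal gains (log₂ ratio ≥ 0.3, ≤ 5 Mb) are
matched to head-to-tail junctions; copies are estimated from coverage,
c = 2·2^log₂ − 2, corrected for enclosing duplications at nested loci, or
from junction support relative to a clonal reference when no coverage
step exists (estimates < 1 suggest sub-clonality). Samples with ≥ 50
matched duplications carry the tandem-duplicator genotype; cohorts of
copy-number profiles can be screened for putative duplicators from gains
alone.

## Worked example

The numbered scripts under `analysis/` run the full study on a synthetic
cohort with planted ground truth (31 libraries, 2,000 genes, 300 planted
16-fold outliers, a labeled fusion-candidate table, three 6-breakpoint
chains and a 241-duplication tandem-duplicator genome):

```sh
python analysis/01_simulate_cohort.py
python analysis/02_outlier_expression.py
python analysis/03_pathway_enrichment.py
python analysis/04_fusion_landscape.py
python analysis/05_tandem_duplications.py
```

which prints (seed 1):

```
713 outlier calls across 31 libraries (581 up, 132 down)
lower-median outliers per sample: 23
planted recovery: sensitivity 0.962, up-direction FDP 0.007
...
80 candidates -> 38 retained (38 planted true; exact match: True)
DNA corroboration: 38/38 evaluable (>5x), 38/38 with a matching junction
complex rearrangements (>2 breakpoints): 4 (3 with >=6 breakpoints)
...
T4: 238 focal gains, 241 tandem duplications matched (241 planted) -> duplicator=True
  nested duplications: 2; junction-only sub-clonal calls: 5 (planted 5)
cohort screen: 1/20 profiles flagged (T4:confirmed)
```

Sensitivity 0.962 means 577 of the 600 planted (gene, sample) outlier
events were recovered; the 38 retained fusion candidates are exactly the
planted true fusions (every artifact class fails precisely the criterion
it was designed to violate); and the tandem-duplicator genome is fully
reconstructed, including the nested serial locus and the five sub-clonal
junctions detectable only through depressed junction support. Tables are
written under `results/`.

The same stages are available as a CLI (`htx simulate | outliers |
enrich | fusions | tandemdup | run`) and as an end-to-end driver
(`htx run --config cfg.json`) producing a deterministic JSON cohort
report.

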