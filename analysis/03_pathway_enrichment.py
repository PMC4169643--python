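#!/usr/bin/env python
"""Gene-set over-representation of each sample's outlier genes.

Builds a small GMT collection over the cohort's gene universe — three
"planted" pathways seeded from the outlier genes of specific samples plus
random background sets — and tests every sample's outlier set against it
(hypergeometric tail, BH-adjusted per sample). The pathway score is
-log10(adjusted p); scores above 1 (adjusted p < 0.1) are displayed.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from htx.formats_io import GeneSetCollection, read_count_matrix, write_gmt
from htx.geneset_enrichment import enrich_cohort

ROOT = Path(__file__).resolve().parents[1]
COHORT = ROOT / "results" / "cohort"
OUT = ROOT / "results"
SEED = 1


def main() -> None:
    cm = read_count_matrix(COHORT / "counts.tsv")
    calls = pd.read_csv(OUT / "outlier_calls.tsv", sep="\t")
    by_sample = {
        sid: set(calls.loc[calls.sample_id == sid, "gene_id"])
        for sid in cm.sample_ids
    }

    rng = np.random.default_rng(SEED)
    sets: dict[str, frozenset] = {}
    seeded = []
    for i, sid in enumerate(cm.sample_ids[:3]):
        core = sorted(by_sample[sid])[:15]
        pad = rng.choice(cm.gene_ids, size=10, replace=False)
        sets[f"seeded_pathway_{sid}"] = frozenset(core) | frozenset(pad)
        seeded.append((sid, f"seeded_pathway_{sid}"))
    for i in range(12):
        sets[f"background_{i:02d}"] = frozenset(
            rng.choice(cm.gene_ids, size=25, replace=False)
        )
    collection = GeneSetCollection(sets)
    write_gmt(collection, COHORT / "pathways.gmt")

    results = enrich_cohort(by_sample, collection, cm.gene_ids)
    df = pd.DataFrame(
        [(r.sample_id, r.set_name, r.overlap, r.set_size, r.query_size,
          r.p_value, r.p_bh, r.pathway_score, r.shown) for r in results],
        columns=["sample_id", "set_name", "overlap", "set_size", "query_size",
                 "p_value", "p_bh", "pathway_score", "shown"],
    )
    df.to_csv(OUT / "enrichment.tsv", sep="\t", index=False)

    shown = df[df.shown]
    n_enriched = shown.sample_id.nunique()
    print(f"{n_enriched}/{cm.n_samples} samples show at least one pathway "
          f"with score > 1 (adjusted p < 0.1)")
    for sid, name in seeded:
        row = df[(df.sample_id == sid) & (df.set_name == name)].iloc[0]
        print(f"  {sid}: {name} score {row.pathway_score:.2f} "
              f"(overlap {row.overlap}/{row.set_size}, shown={row.shown})")


if __name__ == "__main__":
    main()
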