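"""Over-representation analysis of per-sample outlier gene sets.

Each sample's outlier genes are tested against every set of a GMT
collection with the hypergeometric upper tail, Benjamini-Hochberg adjusted
across the sets tested for that sample. The pathway score is
-log10(adjusted p); a result is displayed when the score exceeds 1,
i.e. adjusted p < 0.1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .formats_io import GeneSetCollection, ValidationError

__all__ = [
    "EnrichmentResult",
    "hypergeometric_p",
    "bh_adjust",
    "enrich_sample",
]


@dataclass
class EnrichmentResult:
    sample_id: str
    set_name: str
    overlap: int        # k
    set_size: int       # K (within universe)
    query_size: int     # n (within universe)
    universe_size: int  # N
    p_value: float
    p_bh: float
    pathway_score: float
    shown: bool


def hypergeometric_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n), exact."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError(f"infeasible hypergeometric arguments K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValidationError(f"overlap k={k} outside [0, min({K}, {n})]")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("p values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_sample(
    outlier_genes: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
) -> list[EnrichmentResult]:
    """Test one sample's outlier gene set against every collection set.

    Genes outside the universe are ignored on both sides; BH adjustment is
    across all sets tested for this sample. ``sample_id`` on the results is
    left empty for the caller to fill (see :func:`enrich_cohort`).
    """
    uni = frozenset(universe)
    if not uni:
        raise ValidationError("empty universe")
    query = frozenset(outlier_genes) & uni
    N, n = len(uni), len(query)
    names = list(collection.sets)
    raw: list[float] = []
    overlaps: list[int] = []
    sizes: list[int] = []
    for name in names:
        members = collection.sets[name] & uni
        k = len(query & members)
        overlaps.append(k)
        sizes.append(len(members))
        raw.append(hypergeometric_p(k, len(members), n, N))
    adjusted = bh_adjust(raw) if names else np.array([])
    results = []
    for name, k, K, p, q in zip(names, overlaps, sizes, raw, adjusted):
        score = -math.log10(q) if q > 0 else math.inf
        results.append(
            EnrichmentResult(
                sample_id="",
                set_name=name,
                overlap=k,
                set_size=K,
                query_size=n,
                universe_size=N,
                p_value=p,
                p_bh=float(q),
                pathway_score=score,
                shown=score > 1.0,
            )
        )
    return results


def enrich_cohort(
    outliers_by_sample: dict[str, set[str]],
    collection: GeneSetCollection,
    universe: Iterable[str],
) -> list[EnrichmentResult]:
    """Run :func:`enrich_sample` for every sample; one BH family per sample."""
    uni = frozenset(universe)
    out: list[EnrichmentResult] = []
    for sample_id in outliers_by_sample:
        for res in enrich_sample(outliers_by_sample[sample_id], collection, uni):
            res.sample_id = sample_id
            out.append(res)
    return out
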