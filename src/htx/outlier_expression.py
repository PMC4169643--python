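"""Per-sample outlier expression calling across a cohort.

The procedure: normalize raw counts by median-of-ratios size factors,
convert to gene-level sequence depth (x-coverage), subtract each library's
background noise (mean intergenic/intronic coverage), and run the
Generalized Extreme Studentized Deviate (ESD) test per gene across samples
on log2(depth + 1). Calls are then gated by depth rules — an upregulated
outlier must exceed ``min_depth`` after noise subtraction, a downregulated
outlier requires the non-outlier mean to exceed it — and genes flagged in
more than a third of the cohort are dropped as recurrent, i.e. not
outlier-like at the cohort level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .formats_io import CountMatrix, GeneModel, ValidationError

__all__ = [
    "SizeFactors",
    "ESDParams",
    "ESDResult",
    "NoiseEstimate",
    "DepthMatrix",
    "OutlierCall",
    "compute_size_factors",
    "counts_to_depth",
    "generalized_esd",
    "call_outliers",
]


@dataclass
class SizeFactors:
    """Per-sample median-of-ratios scale factors (all strictly positive)."""

    sample_ids: list[str]
    factors: np.ndarray

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if np.any(self.factors <= 0) or np.any(~np.isfinite(self.factors)):
            raise ValidationError("size factors must be finite and > 0")


@dataclass
class ESDParams:
    """Parameters of the Generalized ESD test.

    ``r_max`` is the maximum number of outliers tested per vector; it is
    additionally capped at half the cohort size at call time.
    """

    r_max: int = 15
    alpha: float = 0.05
    two_sided: bool = True

    def __post_init__(self) -> None:
        if self.r_max < 1:
            raise ValidationError("r_max must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValidationError("alpha must be in (0, 1)")


@dataclass
class ESDResult:
    """All tested steps of one ESD run plus the declared outlier count."""

    n_outliers: int
    statistics: list[float]       # R_i per step
    critical_values: list[float]  # lambda_i per step
    removed_indices: list[int]    # argmax index removed at each step

    @property
    def outlier_indices(self) -> list[int]:
        return self.removed_indices[: self.n_outliers]


@dataclass
class NoiseEstimate:
    """Per-sample mean background depth over intergenic/intronic regions."""

    sample_ids: list[str]
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        if np.any(self.depths < 0):
            raise ValidationError("background noise depths must be >= 0")

    @classmethod
    def zero(cls, sample_ids: Sequence[str]) -> "NoiseEstimate":
        return cls(list(sample_ids), np.zeros(len(sample_ids)))


@dataclass
class DepthMatrix:
    """Gene x sample normalized sequence depth in x-coverage units."""

    gene_ids: list[str]
    sample_ids: list[str]
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError("depth shape mismatch")
        if np.any(self.depth < 0):
            raise ValidationError("depth values must be >= 0")


@dataclass
class OutlierCall:
    gene_id: str
    sample_id: str
    direction: str  # "up" | "down"
    esd_statistic: float
    critical_value: float
    noise_corrected_depth: float


def compute_size_factors(counts: CountMatrix) -> SizeFactors:
    """Median-of-ratios normalization.

    The pseudo-reference for gene i is the geometric mean of its counts
    across samples; s_j is the median over genes of k_ij / reference_i.
    Genes with any zero count are excluded (their geometric mean is zero).
    """
    k = counts.counts.astype(float)
    all_pos = np.all(k > 0, axis=1)
    if not np.any(all_pos):
        raise ValidationError(
            "no gene has all-positive counts; median-of-ratios reference is "
            "undefined (pseudo-reference fallback is disabled)"
        )
    logk = np.log(k[all_pos])
    log_ref = logk.mean(axis=1, keepdims=True)
    ratios = np.exp(logk - log_ref)
    factors = np.median(ratios, axis=0)
    return SizeFactors(list(counts.sample_ids), factors)


def counts_to_depth(
    counts: CountMatrix,
    sf: SizeFactors,
    models: Mapping[str, GeneModel],
    read_length: int = 100,
) -> DepthMatrix:
    """Convert normalized counts to x-coverage: (k/s) * read_length / gene_length."""
    if sf.sample_ids != counts.sample_ids:
        raise ValidationError("size factor samples do not match count matrix")
    missing = [g for g in counts.gene_ids if g not in models]
    if missing:
        raise ValidationError(f"genes without a model: {missing[:10]}")
    lengths = np.array([models[g].gene_length for g in counts.gene_ids], dtype=float)
    if np.any(lengths <= 0):
        raise ValidationError("gene models with non-positive length")
    norm = counts.counts / sf.factors[np.newaxis, :]
    depth = norm * read_length / lengths[:, np.newaxis]
    return DepthMatrix(list(counts.gene_ids), list(counts.sample_ids), depth)


def _esd_critical_values(n: int, r: int, alpha: float, two_sided: bool) -> np.ndarray:
    """lambda_i for i = 1..r at sample size n (Rosner's t-based approximation)."""
    i = np.arange(1, r + 1)
    df = n - i - 1
    if two_sided:
        p = 1.0 - alpha / (2.0 * (n - i + 1))
    else:
        p = 1.0 - alpha / (n - i + 1)
    t = stats.t.ppf(p, df)
    return (n - i) * t / np.sqrt((df + t**2) * (n - i + 1))


_CRIT_CACHE: dict[tuple[int, int, float, bool], np.ndarray] = {}


def generalized_esd(values: Sequence[float], params: ESDParams) -> ESDResult:
    """Rosner's Generalized ESD test for up to ``r_max`` outliers.

    At step i the extreme studentized deviate R_i = max |x - mean| / sd is
    computed on the remaining data and the extreme point removed; the
    declared outlier count is the largest i with R_i > lambda_i. A zero
    standard deviation stops the recursion (degenerate data, no outliers
    beyond that point).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValidationError("Generalized ESD requires at least 3 observations")
    r = min(params.r_max, n // 2, n - 2)
    key = (n, r, params.alpha, params.two_sided)
    lam = _CRIT_CACHE.get(key)
    if lam is None:
        lam = _esd_critical_values(n, r, params.alpha, params.two_sided)
        _CRIT_CACHE[key] = lam

    remaining = np.arange(n)
    stats_out: list[float] = []
    removed: list[int] = []
    for i in range(r):
        sub = x[remaining]
        m = sub.mean()
        s = sub.std(ddof=1)
        if s == 0.0:
            break
        dev = np.abs(sub - m)
        k = int(np.argmax(dev))  # ties: lowest position wins
        stats_out.append(float(dev[k] / s))
        removed.append(int(remaining[k]))
        remaining = np.delete(remaining, k)

    n_steps = len(stats_out)
    crit = [float(v) for v in lam[:n_steps]]
    n_out = 0
    for i in range(n_steps):
        if stats_out[i] > crit[i]:
            n_out = i + 1
    return ESDResult(n_out, stats_out, crit, removed)


def call_outliers(
    depth: DepthMatrix,
    noise: NoiseEstimate,
    params: ESDParams | None = None,
    min_depth: float = 10.0,
    recurrence_fraction: float = 1.0 / 3.0,
    log_transform: bool = True,
) -> list[OutlierCall]:
    """Call per-sample outlier genes across the cohort.

    Per gene: subtract each library's background noise from its depth
    (clamping at zero), transform to log2(depth + 1), and run the ESD test
    across samples. Flagged samples become calls with direction given by
    the sign of the deviation from the non-flagged mean. Up-calls require
    noise-corrected depth > ``min_depth``; down-calls require the mean
    corrected depth of non-outlier samples > ``min_depth``. Genes flagged
    in more than floor(recurrence_fraction * n_samples) libraries are not
    outlier-like at the cohort level and are dropped entirely.
    """
    if params is None:
        params = ESDParams()
    if noise.sample_ids != depth.sample_ids:
        raise ValidationError("noise estimate samples do not match depth matrix")
    n_samples = len(depth.sample_ids)
    max_flagged = int(math.floor(recurrence_fraction * n_samples))
    corrected = np.maximum(depth.depth - noise.depths[np.newaxis, :], 0.0)
    x_all = np.log2(corrected + 1.0) if log_transform else corrected

    calls: list[OutlierCall] = []
    for gi, gene in enumerate(depth.gene_ids):
        x = x_all[gi]
        res = generalized_esd(x, params)
        if res.n_outliers == 0 or res.n_outliers > max_flagged:
            continue
        flagged = res.outlier_indices
        non_flagged = np.setdiff1d(np.arange(n_samples), flagged)
        baseline = float(x[non_flagged].mean())
        mean_bg_depth = float(corrected[gi, non_flagged].mean())
        for step, j in enumerate(flagged):
            direction = "up" if x[j] > baseline else "down"
            if direction == "up" and corrected[gi, j] <= min_depth:
                continue
            if direction == "down" and mean_bg_depth <= min_depth:
                continue
            calls.append(
                OutlierCall(
                    gene_id=gene,
                    sample_id=depth.sample_ids[j],
                    direction=direction,
                    esd_statistic=res.statistics[step],
                    critical_value=res.critical_values[step],
                    noise_corrected_depth=float(corrected[gi, j]),
                )
            )
    return calls
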