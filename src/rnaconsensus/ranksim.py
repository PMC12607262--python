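"""Ranking-similarity metrics and the random-ranking null model.

Rankings here are strict permutations of a common item set (score ties are
broken deterministically upstream, before any metric is computed).  Four
metrics are provided:

* Spearman's rho     rho = 1 - 6 * sum(d^2) / (k (k^2 - 1))
* Kendall's tau      tau = (concordant - discordant) / (k (k-1) / 2)
* Enrichment score   ES  = |top_f(r1) & top_f(r2)| / (f^2 * k)
* Rank-biased overlap (extrapolated)
                     RBO = (1-p) * sum_d p^(d-1) A_d + p^k A_k

The null model draws batches of independent uniform random permutation
pairs, averages each metric within a batch, and reports the empirical 95%
interval of the batch means — the behaviour of a random ranker.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RankSimilarity",
    "NullModelCI",
    "EffectSize",
    "spearman_rho",
    "kendall_tau",
    "enrichment_score",
    "rank_biased_overlap",
    "ranking_similarity",
    "null_model_ci",
    "null_metric_samples",
    "effect_size",
    "significance_profile",
    "METRICS",
]

METRICS = ("spearman", "kendall", "es", "rbo")

DEFAULT_RBO_P = 0.9
DEFAULT_ES_FRACTION = 0.25


@dataclass(frozen=True)
class RankSimilarity:
    rho: float
    tau: float
    es: float
    rbo: float

    def as_dict(self) -> dict[str, float]:
        return {"spearman": self.rho, "kendall": self.tau, "es": self.es,
                "rbo": self.rbo}


@dataclass
class NullModelCI:
    n_items: int
    pairs_per_batch: int
    n_batches: int
    seed: int
    bounds: dict[str, tuple[float, float]]  # metric -> (lower, upper)
    null_mean: dict[str, float] = field(default_factory=dict)
    null_sd: dict[str, float] = field(default_factory=dict)  # per-pair sd


@dataclass(frozen=True)
class EffectSize:
    d: float


def _positions(r1: Sequence[Hashable], r2: Sequence[Hashable]) -> tuple[np.ndarray, np.ndarray]:
    """Positions (0-based) of the common item set in each ranking."""
    if len(r1) < 2:
        raise ValueError("rankings need at least two items")
    if len(set(r1)) != len(r1) or len(set(r2)) != len(r2):
        raise ValueError("rankings must not contain duplicate items")
    if set(r1) != set(r2):
        raise ValueError("rankings must cover the same item set")
    pos2 = {item: i for i, item in enumerate(r2)}
    p1 = np.arange(len(r1))
    p2 = np.array([pos2[item] for item in r1])
    return p1, p2


def spearman_rho(r1: Sequence, r2: Sequence) -> float:
    p1, p2 = _positions(r1, r2)
    k = len(p1)
    d2 = float(np.sum((p1 - p2) ** 2))
    return 1.0 - 6.0 * d2 / (k * (k * k - 1))


def kendall_tau(r1: Sequence, r2: Sequence) -> float:
    p1, p2 = _positions(r1, r2)
    k = len(p1)
    s1 = np.sign(p1[:, None] - p1[None, :])
    s2 = np.sign(p2[:, None] - p2[None, :])
    net = float(np.sum(s1 * s2)) / 2  # concordant - discordant
    return net / (k * (k - 1) / 2)


def enrichment_score(
    r1: Sequence, r2: Sequence, top_fraction: float = DEFAULT_ES_FRACTION
) -> float:
    """Top-fraction overlap normalised by f^2 * k.

    With 13 items and f = 0.25 the top set is the first three positions
    and a perfect overlap scores 3 / (0.0625 * 13) ~ 3.69.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    if len(r1) == 0 or len(r2) == 0:
        raise ValueError("rankings must be non-empty")
    _positions(r1, r2)  # validation
    k = len(r1)
    top = max(1, math.floor(top_fraction * k))
    overlap = len(set(r1[:top]) & set(r2[:top]))
    return overlap / (top_fraction**2 * k)


def rank_biased_overlap(
    r1: Sequence, r2: Sequence, p: float = DEFAULT_RBO_P
) -> float:
    """Extrapolated rank-biased overlap of two full same-item rankings."""
    if not 0 <= p < 1:
        raise ValueError("persistence p must be in [0, 1)")
    _positions(r1, r2)
    k = len(r1)
    seen1: set = set()
    seen2: set = set()
    overlap = 0
    total = 0.0
    a_d = 0.0
    for d in range(1, k + 1):
        x1, x2 = r1[d - 1], r2[d - 1]
        if x1 == x2:
            overlap += 1
        else:
            overlap += (x1 in seen2) + (x2 in seen1)
            seen1.add(x1)
            seen2.add(x2)
        a_d = overlap / d
        total += p ** (d - 1) * a_d
    return (1 - p) * total + p**k * a_d


def ranking_similarity(
    r1: Sequence,
    r2: Sequence,
    *,
    rbo_p: float = DEFAULT_RBO_P,
    es_fraction: float = DEFAULT_ES_FRACTION,
) -> RankSimilarity:
    return RankSimilarity(
        rho=spearman_rho(r1, r2),
        tau=kendall_tau(r1, r2),
        es=enrichment_score(r1, r2, es_fraction),
        rbo=rank_biased_overlap(r1, r2, rbo_p),
    )


# ---------------------------------------------------------------------------
# vectorised batch computation (positions arrays of shape (m, k))


def _batch_spearman(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    k = p1.shape[1]
    d2 = np.sum((p1 - p2) ** 2, axis=1)
    return 1.0 - 6.0 * d2 / (k * (k * k - 1))


def _batch_kendall(p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    k = p1.shape[1]
    s1 = np.sign(p1[:, :, None] - p1[:, None, :])
    s2 = np.sign(p2[:, :, None] - p2[:, None, :])
    net = np.sum(s1 * s2, axis=(1, 2)) / 2
    return net / (k * (k - 1) / 2)


def _batch_es(p1: np.ndarray, p2: np.ndarray, f: float) -> np.ndarray:
    k = p1.shape[1]
    top = max(1, math.floor(f * k))
    overlap = np.sum((p1 < top) & (p2 < top), axis=1)
    return overlap / (f * f * k)


def _batch_rbo(p1: np.ndarray, p2: np.ndarray, p: float) -> np.ndarray:
    k = p1.shape[1]
    m = np.maximum(p1, p2)  # item in both depth-d prefixes iff max pos < d
    depths = np.arange(1, k + 1)
    counts = (m[:, :, None] < depths[None, None, :]).sum(axis=1)
    a = counts / depths
    w = p ** (depths - 1)
    return (1 - p) * (a * w).sum(axis=1) + p**k * a[:, -1]


_BATCH_FUNCS = {
    "spearman": lambda p1, p2, rbo_p, f: _batch_spearman(p1, p2),
    "kendall": lambda p1, p2, rbo_p, f: _batch_kendall(p1, p2),
    "es": lambda p1, p2, rbo_p, f: _batch_es(p1, p2, f),
    "rbo": lambda p1, p2, rbo_p, f: _batch_rbo(p1, p2, rbo_p),
}


def _random_positions(rng: np.random.Generator, m: int, k: int) -> np.ndarray:
    return np.argsort(rng.random((m, k)), axis=1)


def null_metric_samples(
    n_items: int,
    n_pairs: int,
    seed: int,
    metrics: Sequence[str] = METRICS,
    *,
    rbo_p: float = DEFAULT_RBO_P,
    es_fraction: float = DEFAULT_ES_FRACTION,
) -> dict[str, np.ndarray]:
    """Per-pair metric values for n_pairs random ranking pairs."""
    rng = np.random.default_rng(seed)
    p1 = _random_positions(rng, n_pairs, n_items)
    p2 = _random_positions(rng, n_pairs, n_items)
    return {
        m: _BATCH_FUNCS[m](p1, p2, rbo_p, es_fraction) for m in metrics
    }


def null_model_ci(
    n_items: int,
    pairs_per_batch: int,
    n_batches: int,
    seed: int,
    metrics: Sequence[str] = METRICS,
    *,
    rbo_p: float = DEFAULT_RBO_P,
    es_fraction: float = DEFAULT_ES_FRACTION,
) -> NullModelCI:
    """Empirical 95% CI of batch-mean similarity between random rankings.

    Each batch draws ``pairs_per_batch`` independent uniform random pairs of
    ``n_items``-item rankings; per batch the mean of each metric is taken;
    the CI is the [2.5%, 97.5%] percentile interval of the batch means.
    Deterministic under a fixed seed.
    """
    if n_items < 2:
        raise ValueError("n_items must be at least 2")
    unknown = set(metrics) - set(METRICS)
    if unknown:
        raise ValueError(f"unknown metrics: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    means = {m: np.empty(n_batches) for m in metrics}
    sums = {m: 0.0 for m in metrics}
    sumsq = {m: 0.0 for m in metrics}
    for b in range(n_batches):
        p1 = _random_positions(rng, pairs_per_batch, n_items)
        p2 = _random_positions(rng, pairs_per_batch, n_items)
        for m in metrics:
            vals = _BATCH_FUNCS[m](p1, p2, rbo_p, es_fraction)
            means[m][b] = vals.mean()
            sums[m] += float(vals.sum())
            sumsq[m] += float(np.sum(vals * vals))
    n_total = n_batches * pairs_per_batch
    bounds = {}
    null_mean = {}
    null_sd = {}
    for m in metrics:
        lo, hi = np.percentile(means[m], [2.5, 97.5])
        bounds[m] = (float(lo), float(hi))
        mu = sums[m] / n_total
        var = max(sumsq[m] / n_total - mu * mu, 0.0)
        null_mean[m] = mu
        null_sd[m] = math.sqrt(var * n_total / max(n_total - 1, 1))
    return NullModelCI(
        n_items, pairs_per_batch, n_batches, seed, bounds, null_mean, null_sd
    )


# ---------------------------------------------------------------------------
# significance and effect size


def effect_size(
    sample_means: Sequence[float], null_mean: float, null_sd: float
) -> EffectSize:
    """Cohen's d: difference of means over the null-model standard deviation."""
    if null_sd <= 0:
        raise ValueError("effect size undefined for null sd <= 0")
    return EffectSize((float(np.mean(sample_means)) - null_mean) / null_sd)


def significance_profile(
    per_level_samples: Sequence[Sequence[float]],
    null_samples: Sequence[float],
) -> list[tuple[float, float, float]]:
    """Welch's t-test of each noise level against the null distribution,
    Benjamini-Hochberg adjusted across levels.

    Returns one (t statistic, raw p, adjusted p) triple per level.
    """
    null = np.asarray(null_samples, dtype=float)
    if len(null) < 2:
        raise ValueError("need at least two null observations")
    t_stats = []
    raw_p = []
    for sample in per_level_samples:
        sample = np.asarray(sample, dtype=float)
        if len(sample) < 2:
            raise ValueError("need at least two observations per level")
        if sample.std(ddof=1) == 0 and null.std(ddof=1) == 0:
            raise ValueError("zero variance in both groups")
        t, p = stats.ttest_ind(sample, null, equal_var=False)
        t_stats.append(float(t))
        raw_p.append(float(p))
    _, adj_p, _, _ = multipletests(raw_p, method="fdr_bh")
    return list(zip(t_stats, raw_p, map(float, adj_p)))
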