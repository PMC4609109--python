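"""Gene-set enrichment: exact binomial over-representation and a ranked
weighted running-sum (Kolmogorov-Smirnov-style) statistic with
permutation-based significance.

Two flavors mirror the two uses in the analysis:

* :class:`BinomialEnrichment` tests a *selected gene list* (e.g. the top
  loaded genes of a principal component) for over-representation of each
  annotation set, with an exact binomial tail and Bonferroni correction.
* :class:`RankedEnrichment` scores each set against a *ranked* per-gene
  contrast: members accumulate weight proportional to |delta|^p while
  non-members contribute a constant decrement; the enrichment score (ES) is
  the largest absolute excursion of the running sum.  Significance comes
  from gene-label permutations (with 2-3 replicates per condition, sample
  permutation would be degenerate), NES normalizes by the mean same-signed
  null ES, and FDR q-values use the standard positive/negative NES ratio
  method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.base import BaseEstimator

from .comparative import DeltaProfile

__all__ = [
    "EnrichmentResult",
    "binomial_tail_p",
    "filter_sets",
    "BinomialEnrichment",
    "binomial_enrichment",
    "RankedEnrichment",
    "ranked_enrichment",
    "enrichment_score",
]

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    """One gene set's enrichment outcome."""

    name: str
    n_set: int                 # set size within the universe
    statistic: float           # overlap k (binomial) or ES (ranked)
    p: float
    adjusted: float            # Bonferroni p or FDR q
    direction: str | None = None  # "up"/"down" for the ranked method
    nes: float | None = None

    def significant(self, alpha: float = 0.001) -> bool:
        return self.adjusted < alpha


def results_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "set": [r.name for r in results],
            "n_set": [r.n_set for r in results],
            "statistic": [r.statistic for r in results],
            "nes": [r.nes for r in results],
            "p": [r.p for r in results],
            "adjusted": [r.adjusted for r in results],
            "direction": [r.direction for r in results],
        }
    )


def binomial_tail_p(k: int, n: int, q: float, alternative: str = "greater") -> float:
    """Exact binomial tail probability P(X >= k), X ~ Binomial(n, q).

    This is the p-value of the over-representation test; the two-sided
    variant doubles the smaller tail.
    """
    if alternative == "greater":
        p = float(binom.sf(k - 1, n, q))
    elif alternative == "two-sided":
        p = float(min(1.0, 2.0 * min(binom.sf(k - 1, n, q), binom.cdf(k, n, q))))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return min(max(p, 0.0), 1.0)


def filter_sets(sets: dict[str, list[str]], universe, min_size: int = 16
                ) -> dict[str, list[str]]:
    """Intersect sets with the universe and drop those below ``min_size``.

    The default keeps sets *comprising more than 15 genes* within the
    analyzed universe, i.e. intersected size >= 16.
    """
    universe = list(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    uni = set(universe)
    out: dict[str, list[str]] = {}
    for name, members in sets.items():
        inter = [g for g in dict.fromkeys(members) if g in uni]
        if len(inter) >= min_size:
            out[name] = inter
    return out


class BinomialEnrichment(BaseEstimator):
    """Exact binomial over-representation test for a selected gene list.

    For a set of size K inside a universe of N genes and a selection of n
    genes with overlap k, the one-sided p-value is P(X >= k) with
    X ~ Binomial(n, K/N).  The Bonferroni multiplier is the number of sets
    tested.

    Parameters
    ----------
    alternative : {"greater", "two-sided"}
        ``"greater"`` (default) tests enrichment only.
    alpha : float
        Significance level applied by :meth:`EnrichmentResult.significant`;
        0.001 by default.
    min_size : int
        Passed to :func:`filter_sets` before testing.
    """

    def __init__(self, alternative: str = "greater", alpha: float = 0.001,
                 min_size: int = 16):
        self.alternative = alternative
        self.alpha = alpha
        self.min_size = min_size

    def fit(self, selected, sets: dict[str, list[str]], universe
            ) -> "BinomialEnrichment":
        universe = list(universe)
        uni = set(universe)
        offenders = [g for g in selected if g not in uni]
        if offenders:
            raise ValueError(f"selected genes outside the universe: {offenders[:10]}")
        selected_set = set(selected)
        n = len(selected_set)
        N = len(uni)
        kept = filter_sets(sets, universe, min_size=self.min_size)
        results: list[EnrichmentResult] = []
        m = len(kept)
        for name, members in kept.items():
            K = len(members)
            k = sum(1 for g in members if g in selected_set)
            p = binomial_tail_p(k, n, K / N, alternative=self.alternative)
            results.append(
                EnrichmentResult(name=name, n_set=K, statistic=float(k), p=p,
                                 adjusted=min(1.0, p * m))
            )
        self.results_ = results
        self.n_selected_ = n
        self.n_universe_ = N
        return self


def binomial_enrichment(selected, sets, universe, alternative: str = "greater",
                        alpha: float = 0.001, min_size: int = 16
                        ) -> list[EnrichmentResult]:
    est = BinomialEnrichment(alternative=alternative, alpha=alpha, min_size=min_size)
    return est.fit(selected, sets, universe).results_


def _es_from_positions(pos: np.ndarray, weights: np.ndarray, total_w: float,
                       n: int) -> float:
    """ES of one set given sorted 0-based hit positions in the ranking.

    The running sum's extrema occur immediately after a hit (candidate
    maxima) or immediately before a hit / at the end of the list (candidate
    minima), so only the hit positions need to be visited.
    """
    k = len(pos)
    miss_unit = 1.0 / (n - k)
    cum_hit = np.cumsum(weights) / total_w
    miss_before = (pos - np.arange(k)) * miss_unit
    after = cum_hit - miss_before          # value just after each hit
    before = np.concatenate(([0.0], cum_hit[:-1])) - miss_before
    max_dev = max(after.max(), 0.0)
    min_dev = min(before.min(), 0.0)       # path starts and ends at 0
    return float(max_dev if max_dev >= -min_dev else min_dev)


def enrichment_score(delta, members, weight_exponent: float = 1.0) -> float:
    """Weighted running-sum enrichment score of one gene set.

    Genes are ranked by delta (descending); member increments are
    proportional to |delta|^weight_exponent, non-member decrements are
    constant.  Returns the signed maximum deviation.  With
    ``weight_exponent=0`` this reduces to the classic KS statistic and is
    invariant to monotone rescaling of the deltas.
    """
    values = delta.values if isinstance(delta, DeltaProfile) else pd.Series(delta)
    ranked = values.sort_values(ascending=False, kind="mergesort")
    n = len(ranked)
    member_set = set(members)
    hit = np.fromiter((g in member_set for g in ranked.index), dtype=bool, count=n)
    k = int(hit.sum())
    if k == 0 or k == n:
        raise ValueError("gene set must be a proper, non-empty subset of the ranking")
    w = np.abs(ranked.to_numpy()) ** weight_exponent
    pos = np.flatnonzero(hit)
    weights = w[pos]
    total = float(weights.sum())
    if total == 0:
        weights = np.ones(k)
        total = float(k)
    return _es_from_positions(pos, weights, total, n)


def _null_es(w: np.ndarray, k: int, n_perm: int, rng: np.random.Generator
             ) -> np.ndarray:
    """Null ES distribution for random sets of size k (gene-label permutation)."""
    n = len(w)
    out = np.empty(n_perm)
    # sample k positions without replacement per permutation via argpartition
    u = rng.random((n_perm, n))
    idx = np.argpartition(u, k - 1, axis=1)[:, :k]
    idx.sort(axis=1)
    miss_unit = 1.0 / (n - k)
    arange_k = np.arange(k)
    for i in range(n_perm):
        pos = idx[i]
        weights = w[pos]
        total = float(weights.sum())
        if total == 0:
            weights = np.ones(k)
            total = float(k)
        cum_hit = np.cumsum(weights) / total
        miss_before = (pos - arange_k) * miss_unit
        after = cum_hit - miss_before
        before = np.concatenate(([0.0], cum_hit[:-1])) - miss_before
        max_dev = max(after.max(), 0.0)
        min_dev = min(before.min(), 0.0)
        out[i] = max_dev if max_dev >= -min_dev else min_dev
    return out


class RankedEnrichment(BaseEstimator):
    """Ranked (running-sum) gene-set enrichment with permutation nulls.

    Parameters
    ----------
    weight_exponent : float
        Exponent p on |delta| for member increments (1 by default).
    n_perm : int
        Gene-label permutations per set size; below 100 a warning is logged.
    min_size : int
        Set-size filter applied before scoring.
    seed : int
        Seed for the permutation RNG.
    """

    def __init__(self, weight_exponent: float = 1.0, n_perm: int = 1000,
                 min_size: int = 16, seed: int = 0):
        self.weight_exponent = weight_exponent
        self.n_perm = n_perm
        self.min_size = min_size
        self.seed = seed

    def fit(self, delta, sets: dict[str, list[str]]) -> "RankedEnrichment":
        if self.n_perm < 100:
            logger.warning("n_perm=%d is low; p-values will be coarse", self.n_perm)
        values = delta.values if isinstance(delta, DeltaProfile) else pd.Series(delta)
        if len(values) == 0:
            raise ValueError("zero-length ranking")
        ranked = values.sort_values(ascending=False, kind="mergesort")
        n = len(ranked)
        kept = filter_sets(sets, ranked.index, min_size=self.min_size)
        if not kept:
            raise ValueError("no gene sets left after size filtering")
        w = np.abs(ranked.to_numpy()) ** self.weight_exponent
        gene_pos = {g: i for i, g in enumerate(ranked.index)}
        rng = np.random.default_rng(np.random.SeedSequence([int(self.seed), 0x65EA]))

        null_cache: dict[int, np.ndarray] = {}
        observed: dict[str, float] = {}
        for name, members in kept.items():
            pos = np.sort(np.fromiter((gene_pos[g] for g in members), dtype=int))
            weights = w[pos]
            total = float(weights.sum())
            if total == 0:
                weights = np.ones(len(pos))
                total = float(len(pos))
            observed[name] = _es_from_positions(pos, weights, total, n)
            k = len(pos)
            if k not in null_cache:
                null_cache[k] = _null_es(w, k, self.n_perm, rng)

        # per-set p and NES against the same-signed side of the null
        nes_obs: dict[str, float] = {}
        p_obs: dict[str, float] = {}
        null_nes_all: list[np.ndarray] = []
        for name, members in kept.items():
            es = observed[name]
            null = null_cache[len(members)]
            if es >= 0:
                side = null[null >= 0]
                p = (1 + int((side >= es).sum())) / (1 + len(side))
                denom = side.mean() if len(side) else np.nan
            else:
                side = null[null < 0]
                p = (1 + int((side <= es).sum())) / (1 + len(side))
                denom = np.abs(side).mean() if len(side) else np.nan
            p_obs[name] = min(p, 1.0)
            nes_obs[name] = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        for k, null in null_cache.items():
            pos_mean = null[null >= 0].mean() if (null >= 0).any() else np.nan
            neg_mean = np.abs(null[null < 0]).mean() if (null < 0).any() else np.nan
            normed = np.where(null >= 0,
                              null / pos_mean if np.isfinite(pos_mean) else np.nan,
                              null / neg_mean if np.isfinite(neg_mean) else np.nan)
            null_nes_all.append(normed[np.isfinite(normed)])
        pooled_null = np.concatenate(null_nes_all)
        obs_nes_values = np.array([nes_obs[name] for name in kept])

        results: list[EnrichmentResult] = []
        for name, members in kept.items():
            es = observed[name]
            nes = nes_obs[name]
            q = self._fdr_q(nes, pooled_null, obs_nes_values)
            results.append(
                EnrichmentResult(
                    name=name, n_set=len(members), statistic=es, p=p_obs[name],
                    adjusted=q, nes=nes,
                    direction="up" if es >= 0 else "down",
                )
            )
        self.results_ = results
        self.ranking_ = ranked
        return self

    @staticmethod
    def _fdr_q(nes: float, pooled_null: np.ndarray, obs_nes: np.ndarray) -> float:
        """Positive/negative NES-ratio FDR estimate."""
        if not np.isfinite(nes):
            return 1.0
        if nes >= 0:
            null_side = pooled_null[pooled_null >= 0]
            obs_side = obs_nes[np.isfinite(obs_nes) & (obs_nes >= 0)]
            null_frac = (null_side >= nes).mean() if len(null_side) else 1.0
            obs_frac = (obs_side >= nes).mean() if len(obs_side) else 1.0
        else:
            null_side = pooled_null[pooled_null < 0]
            obs_side = obs_nes[np.isfinite(obs_nes) & (obs_nes < 0)]
            null_frac = (null_side <= nes).mean() if len(null_side) else 1.0
            obs_frac = (obs_side <= nes).mean() if len(obs_side) else 1.0
        if obs_frac == 0:
            return 1.0
        return float(min(1.0, null_frac / obs_frac))


def ranked_enrichment(delta, sets, weight_exponent: float = 1.0,
                      n_perm: int = 1000, min_size: int = 16, seed: int = 0
                      ) -> list[EnrichmentResult]:
    est = RankedEnrichment(weight_exponent=weight_exponent, n_perm=n_perm,
                           min_size=min_size, seed=seed)
    return est.fit(delta, sets).results_
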