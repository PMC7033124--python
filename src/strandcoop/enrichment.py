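"""Gene set enrichment from first principles.

Three estimators live here:

* the weighted Kolmogorov-Smirnov enrichment score (ES) with its running
  profile and leading-edge ("core enrichment") genes;
* significance via gene-sampling permutation: null ES from random sets of
  matched size on the same ranked list, normalized scores (NES = ES /
  mean |null ES| of matching sign), permutation p-values, and the
  sign-stratified ratio-of-tails FDR;
* single-sample scores (ssGSEA): rank-weighted ECDF differences, and the
  upper-tail hypergeometric over-representation test.

Gene-sampling (rather than phenotype) permutation is the only scheme
available here because each dependency screen supplies a single ranked
list per cell line.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RankedList",
    "EnrichmentResult",
    "enrichment_score",
    "gsea_significance",
    "ssgsea_score",
    "hypergeom_ora",
]


@dataclass
class RankedList:
    """Genes ordered by a ranking metric, descending, ties broken
    lexicographically by gene id for determinism."""

    genes: np.ndarray
    metric: np.ndarray

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=object)
        self.metric = np.asarray(self.metric, dtype=float)
        if self.genes.size != self.metric.size:
            raise ValueError("genes and metric differ in length")
        if len(set(self.genes)) != self.genes.size:
            raise ValueError("duplicate genes in ranked list")

    @classmethod
    def from_scores(cls, scores: pd.Series) -> "RankedList":
        """Build from a gene -> metric Series (NaN entries dropped)."""
        s = scores.dropna()
        order = sorted(s.index, key=lambda g: (-s[g], g))
        return cls(
            genes=np.array(order, dtype=object),
            metric=s.loc[order].to_numpy(dtype=float),
        )

    def positions_of(self, gene_set) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.genes)}
        return np.array(sorted(lookup[g] for g in gene_set if g in lookup), dtype=int)

    def __len__(self) -> int:
        return self.genes.size


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p_value: float
    fdr: float
    leading_edge: tuple
    size: int
    n_permutations: int


def _es_from_positions(
    pos: np.ndarray, metric: np.ndarray, n: int, exponent: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ES for one or many hit-position vectors.

    ``pos`` is (k,) or (B, k) of sorted 0-based hit positions.  Returns
    (es, argext, is_positive): the signed maximal deviation of the
    running P_hit - P_miss statistic, the hit index attaining it, and its
    sign.  The running statistic changes only at hit positions (P_hit
    jumps by the normalized weight) and decreases linearly by
    1/(N - N_H) per miss in between, so the extremum is found from the
    values just after and just before each hit.
    """
    pos2 = np.atleast_2d(pos)
    b, k = pos2.shape
    if k == 0 or k >= n:
        raise ValueError("gene set must hit >=1 and < all ranked genes")
    w = np.abs(metric[pos2]) ** exponent
    wsum = w.sum(axis=1, keepdims=True)
    flat = wsum[:, 0] == 0
    if flat.any():  # all-zero metric: fall back to unweighted statistic
        w[flat] = 1.0
        wsum = w.sum(axis=1, keepdims=True)
    cum = np.cumsum(w, axis=1) / wsum
    d = 1.0 / (n - k)
    i = np.arange(k)
    after = cum - (pos2 - i) * d           # just after hit i
    before = cum - w / wsum - (pos2 - i) * d  # just before hit i
    hi = after.max(axis=1)
    lo = before.min(axis=1)
    positive = hi >= -lo
    es = np.where(positive, np.maximum(hi, 0.0), np.minimum(lo, 0.0))
    argext = np.where(positive, after.argmax(axis=1), before.argmin(axis=1))
    if np.ndim(pos) == 1:
        return es[0], argext[0], positive[0]
    return es, argext, positive


def enrichment_score(
    ranked: RankedList, gene_set, exponent: float = 1.0
) -> tuple[float, np.ndarray, tuple]:
    """Weighted KS enrichment score of ``gene_set`` on ``ranked``.

    Returns ``(es, running_profile, leading_edge)``.  The running
    profile is evaluated just after every list position.  The leading
    edge contains the in-set genes at or before the maximum (ES > 0) or
    at or after the minimum (ES < 0).
    """
    n = len(ranked)
    pos = ranked.positions_of(gene_set)
    if pos.size == 0:
        raise ValueError("gene set is disjoint from the ranked list")
    es, argext, positive = _es_from_positions(pos, ranked.metric, n, exponent)

    # dense running profile (used by tests and plots; O(N))
    w = np.abs(ranked.metric[pos]) ** exponent
    if w.sum() == 0:
        w = np.ones_like(w)
    hit = np.zeros(n)
    hit[pos] = w / w.sum()
    miss = np.full(n, 1.0 / (n - pos.size))
    miss[pos] = 0.0
    profile = np.cumsum(hit - miss)

    if positive:
        leading = tuple(ranked.genes[p] for p in pos[: argext + 1])
    else:
        leading = tuple(ranked.genes[p] for p in pos[argext:])
    return float(es), profile, leading


def _null_positions(
    n: int, k: int, n_perm: int, rng: np.random.Generator, exhaustive: bool
) -> np.ndarray:
    if exhaustive:
        if comb(n, k) > 200_000:
            raise ValueError("exhaustive null too large; use sampling")
        return np.array(list(combinations(range(n), k)), dtype=int)
    draws = rng.random((n_perm, n)).argpartition(k, axis=1)[:, :k]
    return np.sort(draws, axis=1)


def gsea_significance(
    ranked: RankedList,
    gene_sets: dict,
    n_perm: int = 1000,
    seed: int = 0,
    exponent: float = 1.0,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Permutation GSEA of a collection of gene sets on one ranked list.

    Null ES come from random gene sets of matched size drawn from the
    ranked list (exhaustively enumerated when ``exhaustive`` is set and
    feasible).  NES divides each ES by the mean |null ES| of matching
    sign; p is the fraction of same-sign null ES at least as extreme;
    FDR follows the sign-stratified ratio-of-tails procedure with the
    null NES pooled across sets.
    """
    if not exhaustive and n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    n = len(ranked)
    rng = np.random.default_rng(seed)
    names = sorted(gene_sets)
    rows = []
    pooled_null_nes: list[np.ndarray] = []
    null_cache: dict[int, tuple[np.ndarray, float, float]] = {}

    for name in names:
        pos = ranked.positions_of(gene_sets[name])
        if pos.size == 0:
            raise ValueError(f"gene set {name!r} is disjoint from the ranked list")
        if pos.size >= n:
            raise ValueError(f"gene set {name!r} covers the whole ranked list")
        es, _, leading = enrichment_score(ranked, gene_sets[name], exponent)
        k = pos.size
        if k not in null_cache:
            npos = _null_positions(n, k, n_perm, rng, exhaustive)
            null_es, _, _ = _es_from_positions(npos, ranked.metric, n, exponent)
            mean_pos = null_es[null_es > 0].mean() if (null_es > 0).any() else np.nan
            mean_neg = np.abs(null_es[null_es < 0]).mean() if (null_es < 0).any() else np.nan
            null_cache[k] = (null_es, mean_pos, mean_neg)
        null_es, mean_pos, mean_neg = null_cache[k]

        if es >= 0:
            same = null_es[null_es >= 0]
            denom = mean_pos
        else:
            same = null_es[null_es < 0]
            denom = mean_neg
        p = float(np.mean(np.abs(same) >= abs(es) - 1e-12)) if same.size else 1.0
        nes = es / denom if np.isfinite(denom) and denom > 0 else np.nan
        norm = np.where(
            null_es >= 0,
            null_es / (mean_pos if np.isfinite(mean_pos) else np.nan),
            null_es / (mean_neg if np.isfinite(mean_neg) else np.nan),
        )
        pooled_null_nes.append(norm[np.isfinite(norm)])
        rows.append(
            {
                "set_name": name,
                "es": es,
                "nes": nes,
                "p_value": p,
                "size": k,
                "leading_edge": leading,
                "n_permutations": int(null_es.size),
            }
        )

    out = pd.DataFrame(rows).set_index("set_name")
    pooled = np.concatenate(pooled_null_nes) if pooled_null_nes else np.array([])
    out["fdr"] = _ratio_of_tails_fdr(out["nes"].to_numpy(), pooled)
    return out


def _ratio_of_tails_fdr(obs_nes: np.ndarray, null_nes: np.ndarray) -> np.ndarray:
    """Sign-stratified FDR q-values from pooled normalized null scores."""
    q = np.ones(obs_nes.size)
    null_pos = null_nes[null_nes >= 0]
    null_neg = null_nes[null_nes < 0]
    obs_pos = obs_nes[np.isfinite(obs_nes) & (obs_nes >= 0)]
    obs_neg = obs_nes[np.isfinite(obs_nes) & (obs_nes < 0)]
    for i, nes in enumerate(obs_nes):
        if not np.isfinite(nes):
            continue
        if nes >= 0:
            num = np.mean(null_pos >= nes) if null_pos.size else 1.0
            den = np.mean(obs_pos >= nes) if obs_pos.size else 1.0
        else:
            num = np.mean(null_neg <= nes) if null_neg.size else 1.0
            den = np.mean(obs_neg <= nes) if obs_neg.size else 1.0
        q[i] = min(1.0, num / den) if den > 0 else 1.0
    return q


def ssgsea_score(expression: pd.Series, gene_set, alpha: float = 0.25) -> float:
    """Single-sample enrichment score of ``gene_set`` in one expression
    vector.

    Genes are ranked by expression (descending, ties broken by gene id);
    an in-set gene at descending position ``i`` (0-based) carries weight
    ``(N - i) ** alpha``.  The score is the sum over list positions of
    the weighted in-set ECDF minus the out-set ECDF, divided by the list
    length N.  The constant normalizer keeps the score scale-free in N
    while preserving two contracts a per-profile normalizer would break:
    the top-k expressed set attains the maximal score among size-k sets,
    and raising every in-set expression never lowers the score.  The
    statistic is rank-based, hence invariant to monotone transforms.
    """
    s = expression.dropna()
    order = sorted(s.index, key=lambda g: (-s[g], g))
    n = len(order)
    in_set = np.array([g in set(gene_set) for g in order])
    k = int(in_set.sum())
    if k == 0:
        raise ValueError("gene set is disjoint from the expression vector")
    if k == n:
        raise ValueError("gene set covers every measured gene")
    ranks = (n - np.arange(n)).astype(float)
    w = np.where(in_set, ranks**alpha, 0.0)
    p_in = np.cumsum(w) / w.sum()
    p_out = np.cumsum(~in_set) / (n - k)
    diff = p_in - p_out
    return float(diff.sum() / n)


def hypergeom_ora(query, pathway, universe) -> tuple[float, float, set]:
    """Upper-tail hypergeometric over-representation test.

    Returns ``(p, enrichment_ratio, overlap_genes)`` for P(X >= overlap)
    with population ``universe``, successes ``pathway & universe`` and
    draws ``query``.  The query must be a subset of the universe.
    """
    universe = set(universe)
    query = set(query)
    if not query <= universe:
        raise ValueError("query genes must lie in the universe")
    hits = set(pathway) & universe
    if not hits:
        raise ValueError("pathway has no genes in the universe")
    if not query:
        return 1.0, float("nan"), set()
    overlap = query & hits
    m, big_k, small_n, k = len(universe), len(hits), len(query), len(overlap)
    p = float(stats.hypergeom.sf(k - 1, m, big_k, small_n))
    ratio = (k / small_n) / (big_k / m)
    return p, ratio, overlap
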