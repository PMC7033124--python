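"""Tumor-vs-normal differential expression with negative-binomial exact tests.

The analysis path is the classic count-based one: trimmed-mean-of-M-values
(TMM) library normalization, a single common dispersion estimated by
conditional maximum likelihood on library-size-equalized pseudo-counts,
and a two-sided exact test that conditions on each feature's pseudo-total
(the NB analogue of Fisher's exact test; at dispersion 0 it reduces to the
exact binomial test).  Fold changes are computed on the normalized matrix
with a 0.5 pseudo-count, and calls use the fold/alpha thresholds of the
pipeline configuration (1.5-fold for miRNA, 2-fold for mRNA, BH p < 0.05).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .datatypes import ExpressionStudy, TUMOR, NORMAL

__all__ = [
    "filter_expressed",
    "tmm_factors",
    "estimate_common_dispersion",
    "nb_exact_test",
    "bh_adjust",
    "call_differential",
    "log2_fold_change",
    "spearman",
    "spearman_pairs",
    "CorrelationResult",
    "differential_expression",
]


def filter_expressed(
    study: ExpressionStudy, min_value: float = 1.0, min_fraction: float = 0.5
) -> ExpressionStudy:
    """Keep features with normalized expression >= ``min_value`` in at
    least ``ceil(min_fraction * n_samples)`` samples.

    Raw and normalized matrices are subset identically.  An empty result
    is allowed (downstream stages treat it as "nothing expressed").
    """
    n = study.normalized.shape[1]
    need = math.ceil(min_fraction * n)
    ok = (study.normalized >= min_value).sum(axis=1) >= need
    return study.subset_features(study.features[ok.to_numpy()])


def tmm_factors(raw_counts: pd.DataFrame) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    The reference sample is the column whose upper-quartile expression
    (counts scaled by library size) is closest to the mean upper
    quartile.  M-values are trimmed 30% (two-sided) and A-values 5%
    before the precision-weighted mean is taken.
    """
    counts = raw_counts.to_numpy(dtype=float)
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        bad = raw_counts.columns[lib == 0].tolist()
        raise ValueError(f"all-zero samples: {bad}")
    f75 = np.array([np.quantile(counts[:, j] / lib[j], 0.75) for j in range(counts.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(counts.shape[1])
    yr, nr = counts[:, ref], lib[ref]
    for j in range(counts.shape[1]):
        if j == ref:
            continue
        factors[j] = _tmm_one(counts[:, j], lib[j], yr, nr)
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=raw_counts.columns, name="tmm_factor")


def _tmm_one(y, n, yr, nr, log_ratio_trim=0.3, sum_trim=0.05):
    keep = (y > 0) & (yr > 0)
    y, yr_ = y[keep], yr[keep]
    m = np.log2((y / n) / (yr_ / nr))
    a = 0.5 * np.log2((y / n) * (yr_ / nr))
    w = (n - y) / (n * y) + (nr - yr_) / (nr * yr_)
    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0
    k = m.size
    lo_l = math.floor(k * log_ratio_trim) + 1
    hi_l = k + 1 - lo_l
    lo_s = math.floor(k * sum_trim) + 1
    hi_s = k + 1 - lo_s
    rm = stats.rankdata(m)
    ra = stats.rankdata(a)
    keep2 = (rm >= lo_l) & (rm <= hi_l) & (ra >= lo_s) & (ra <= hi_s)
    if not keep2.any():
        return 1.0
    mean_m = np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    if not np.isfinite(mean_m):
        return 1.0
    return 2.0 ** mean_m


def _pseudo_counts(raw_counts: pd.DataFrame, factors: pd.Series) -> np.ndarray:
    """Scale each sample's counts to the geometric-mean effective library size."""
    counts = raw_counts.to_numpy(dtype=float)
    eff = counts.sum(axis=0) * factors.loc[raw_counts.columns].to_numpy()
    target = np.exp(np.mean(np.log(eff)))
    return counts * (target / eff)


def _conditional_loglik(pseudo: np.ndarray, group_masks, phi: float) -> float:
    """Quantile-adjusted conditional NB log-likelihood at dispersion ``phi``.

    For each group of n samples, conditioning each feature on its group
    total leaves a likelihood free of the mean parameter; terms constant
    in phi are dropped.
    """
    r = 1.0 / phi
    total = 0.0
    for mask in group_masks:
        y = pseudo[:, mask]
        n = y.shape[1]
        z = y.sum(axis=1)
        total += float(
            np.sum(special.gammaln(y + r))
            - y.size * special.gammaln(r)
            + y.shape[0] * special.gammaln(n * r)
            - np.sum(special.gammaln(z + n * r))
        )
    return total


def estimate_common_dispersion(
    raw_counts: pd.DataFrame, groups: pd.Series, factors: pd.Series | None = None
) -> float:
    """Common NB dispersion by conditional maximum likelihood.

    Maximizes the conditional likelihood on pseudo-counts over a
    log-spaced grid refined by bounded golden-section search; returns 0
    when the Poisson limit fits at least as well.
    """
    groups = groups.loc[raw_counts.columns]
    masks = [
        (groups == g).to_numpy() for g in (TUMOR, NORMAL) if (groups == g).sum() >= 2
    ]
    if not masks:
        raise ValueError("need at least one group with >=2 samples")
    if factors is None:
        factors = tmm_factors(raw_counts)
    pseudo = _pseudo_counts(raw_counts, factors)
    pseudo = pseudo[pseudo.sum(axis=1) > 0]
    if pseudo.size == 0:
        return 0.0

    grid = np.logspace(-6, 1, 30)
    lls = np.array([_conditional_loglik(pseudo, masks, p) for p in grid])
    best = int(np.argmax(lls))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        lambda logphi: -_conditional_loglik(pseudo, masks, math.exp(logphi)),
        bounds=(math.log(lo), math.log(hi)),
        method="bounded",
        options={"xatol": 1e-6},
    )
    phi = math.exp(res.x)
    if _conditional_loglik(pseudo, masks, 1e-10) >= -res.fun:
        return 0.0
    return phi


def _exact_p_one(z1: float, z2: float, n1: int, n2: int, phi: float) -> float:
    """Two-sided conditional exact p for one feature's group totals."""
    z1, z2 = int(round(z1)), int(round(z2))
    z = z1 + z2
    if z == 0:
        return 1.0
    k = np.arange(z + 1)
    if phi <= 0:
        logp = stats.binom.logpmf(k, z, n1 / (n1 + n2))
    else:
        r1, r2 = n1 / phi, n2 / phi
        logp = (
            special.gammaln(k + r1)
            - special.gammaln(k + 1)
            + special.gammaln(z - k + r2)
            - special.gammaln(z - k + 1)
        )
        logp -= special.logsumexp(logp)
    obs = logp[z1]
    p = float(np.exp(special.logsumexp(logp[logp <= obs + 1e-10])))
    return min(p, 1.0)


def nb_exact_test(
    raw_counts: pd.DataFrame,
    groups: pd.Series,
    factors: pd.Series | None = None,
    phi: float = 0.0,
) -> pd.Series:
    """Per-feature two-sided NB exact test p-values (tumor vs normal).

    Counts are first equalized to a common library size (pseudo-counts),
    group totals are rounded, and the conditional distribution of the
    tumor total given the feature total is summed over all outcomes at
    most as probable as the observed split.
    """
    groups = groups.loc[raw_counts.columns]
    if factors is None:
        factors = tmm_factors(raw_counts)
    pseudo = _pseudo_counts(raw_counts, factors)
    mask1 = (groups == TUMOR).to_numpy()
    mask2 = (groups == NORMAL).to_numpy()
    n1, n2 = int(mask1.sum()), int(mask2.sum())
    if n1 == 0 or n2 == 0:
        raise ValueError("both tumor and normal samples are required")
    z1 = pseudo[:, mask1].sum(axis=1)
    z2 = pseudo[:, mask2].sum(axis=1)
    pvals = np.array([_exact_p_one(a, b, n1, n2, phi) for a, b in zip(z1, z2)])
    return pd.Series(pvals, index=raw_counts.index, name="p_value")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_differential(
    log2fc, adj_p, fold_threshold: float, alpha: float = 0.05
) -> np.ndarray:
    """Vectorized up/down/ns calls from fold changes and adjusted p-values."""
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    log2fc = np.asarray(log2fc, dtype=float)
    adj_p = np.asarray(adj_p, dtype=float)
    cut = math.log2(fold_threshold)
    call = np.full(log2fc.shape, "ns", dtype=object)
    sig = adj_p < alpha
    call[sig & (log2fc >= cut)] = "up"
    call[sig & (log2fc <= -cut)] = "down"
    return call


def log2_fold_change(study: ExpressionStudy, pseudo: float = 0.5) -> pd.Series:
    """log2 of (mean normalized tumor + pseudo) / (mean normalized normal + pseudo)."""
    t = study.normalized[study.tumor_samples].mean(axis=1)
    n = study.normalized[study.normal_samples].mean(axis=1)
    return np.log2((t + pseudo) / (n + pseudo)).rename("log2fc")


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    valid: bool = True


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with average-rank ties.

    p-values come from the t approximation, except for n <= 9 where the
    exact permutation distribution is enumerated.  A constant input
    vector makes rho undefined; the result is flagged invalid.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(rho=float("nan"), p_value=float("nan"), n=n, valid=False)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 9:
        null = np.array(
            [np.corrcoef(rx, perm)[0, 1] for perm in permutations(ry)]
        )
        p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return CorrelationResult(rho=rho, p_value=p, n=n)


def _rank_z(matrix: np.ndarray) -> np.ndarray:
    """Row-wise average ranks, centered and scaled to unit norm."""
    ranks = np.apply_along_axis(stats.rankdata, 1, matrix)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(ranks, axis=1, keepdims=True)
    norm[norm == 0] = np.nan
    return ranks / norm


def spearman_pairs(x_matrix: np.ndarray, y_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-aligned Spearman rho and t-approximation p for many pairs at once.

    ``x_matrix`` and ``y_matrix`` are (pairs x samples); row i of one is
    correlated with row i of the other.  Constant rows yield NaN.
    """
    zx = _rank_z(np.asarray(x_matrix, dtype=float))
    zy = _rank_z(np.asarray(y_matrix, dtype=float))
    rho = np.sum(zx * zy, axis=1)
    n = x_matrix.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / np.clip(1 - rho**2, 1e-300, None))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(rho), 1.0)] = 0.0
    return rho, p


def differential_expression(
    study: ExpressionStudy, config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Full DE table for one study: filter, normalize, test, adjust, call.

    Returns a DataFrame indexed by feature with columns ``log2fc``,
    ``p_value``, ``adj_p`` and ``call``.  The expression filter is applied
    on the normalized matrix first; testing then runs on raw counts of the
    surviving features.
    """
    config = config or PipelineConfig()
    study = filter_expressed(study, config.expr_min_value, config.expr_min_fraction)
    fold_threshold = (
        config.mirna_fold_threshold
        if study.feature_kind == "miRNA"
        else config.mrna_fold_threshold
    )
    if len(study.features) == 0:
        return pd.DataFrame(columns=["log2fc", "p_value", "adj_p", "call"])
    factors = tmm_factors(study.raw_counts)
    phi = estimate_common_dispersion(study.raw_counts, study.sample_groups, factors)
    p = nb_exact_test(study.raw_counts, study.sample_groups, factors, phi)
    lfc = log2_fold_change(study, config.pseudo_fold)
    adj = bh_adjust(p.to_numpy())
    out = pd.DataFrame(
        {
            "log2fc": lfc,
            "p_value": p,
            "adj_p": adj,
            "call": call_differential(lfc, adj, fold_threshold, config.alpha),
        }
    )
    out.attrs["common_dispersion"] = phi
    return out
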