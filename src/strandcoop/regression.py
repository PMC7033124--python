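"""Confounder-adjusted miRNA-mRNA association and cross-cancer recurrence.

Per (gene, miRNA, cancer) an ordinary least-squares fit

    Y_s = b0 + b_DM * x_DM,s + b_CNV * x_CNV,s + b_miR * x_miR,s

separates the miRNA association from DNA-methylation and copy-number
effects; Y is log2(normalized mRNA + 1) in the tumor samples and the
covariates are standardized per cancer so the miRNA coefficients are
comparable across cancers.  Coefficients collated over cancers feed the
rank-product statistic (geometric mean of per-cancer ranks, most
negative first for the inverse direction) with a column-permutation
Monte Carlo p-value and BH correction.  The essential-gene depletion
check (two-sample KS) closes the loop against perturbation profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

__all__ = [
    "RegressionFit",
    "fit_multivariate",
    "coefficient_matrix",
    "rank_product",
    "essential_depletion_test",
]

_COND_LIMIT = 1e8


@dataclass
class RegressionFit:
    beta_0: float
    beta_dm: float
    beta_cnv: float
    beta_mir: float
    se_mir: float
    p_mir: float
    n: int
    collinear: bool = False


def fit_multivariate(y, x_dm, x_cnv, x_mir) -> RegressionFit:
    """OLS fit of the four-term model; two-sided t test on the miRNA slope.

    Requires n >= 8.  A design matrix with condition number above 1e8 is
    flagged collinear (no inference; the fit is excluded from recurrence
    by the caller).
    """
    y = np.asarray(y, dtype=float)
    x = np.column_stack(
        [np.ones_like(y), np.asarray(x_dm, float), np.asarray(x_cnv, float),
         np.asarray(x_mir, float)]
    )
    n = y.size
    if n < 8:
        raise ValueError("need at least 8 samples")
    if np.linalg.cond(x) > _COND_LIMIT:
        return RegressionFit(*([float("nan")] * 6), n=n, collinear=True)
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    df = n - 4
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(x.T @ x)
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[3] / se[3] if se[3] > 0 else np.inf * np.sign(beta[3])
    p = float(2 * stats.t.sf(abs(t), df=df)) if np.isfinite(t) else 0.0
    return RegressionFit(
        beta_0=float(beta[0]),
        beta_dm=float(beta[1]),
        beta_cnv=float(beta[2]),
        beta_mir=float(beta[3]),
        se_mir=float(se[3]),
        p_mir=p,
        n=n,
    )


def coefficient_matrix(fits: pd.DataFrame) -> pd.DataFrame:
    """Collate per-cancer miRNA coefficients into (gene, miRNA) x cancer.

    ``fits`` needs columns ``gene``, ``mirna``, ``cancer`` and
    ``beta_mir``; collinear fits should be excluded beforehand.  Missing
    cells stay NaN; rows observed in fewer than 2 cancers are dropped.
    """
    wide = fits.pivot_table(
        index=["gene", "mirna"], columns="cancer", values="beta_mir", aggfunc="first"
    )
    return wide[wide.notna().sum(axis=1) >= 2]


def _row_rank_product(ranked: np.ndarray) -> np.ndarray:
    """Geometric mean of each row's available (non-NaN) ranks."""
    with np.errstate(invalid="ignore"):
        logs = np.log(ranked)
    k = np.sum(~np.isnan(ranked), axis=1)
    return np.exp(np.nansum(logs, axis=1) / np.maximum(k, 1))


def rank_product(
    matrix: pd.DataFrame,
    direction: str = "inverse",
    n_perm: int = 10_000,
    seed: int = 0,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Rank-product recurrence test over a (rows x studies) value matrix.

    ``direction="inverse"`` ranks the most negative value 1 in every
    column, ``"positive"`` the most positive.  RP is the geometric mean
    of a row's per-column ranks (missing cells are ranked within the
    column's observed rows and k is recorded).  The p-value is the
    permutation estimate P(RP_null <= RP_obs) where the null shuffles
    each column's ranks independently among its observed rows; rows are
    compared only against null rows sharing their missingness pattern.
    ``exhaustive`` enumerates every combination of per-column
    permutations (feasible only for tiny matrices) instead of Monte
    Carlo sampling.  BH is applied across rows.
    """
    if direction not in ("inverse", "positive"):
        raise ValueError("direction must be 'inverse' or 'positive'")
    if not exhaustive and n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    values = matrix.to_numpy(dtype=float)
    if direction == "positive":
        values = -values
    n_rows, n_cols = values.shape
    if n_rows < 2 or n_cols < 2:
        raise ValueError("need at least 2 rows and 2 studies")

    ranks = np.full_like(values, np.nan)
    col_pools = []
    for j in range(n_cols):
        obs = np.isfinite(values[:, j])
        r = stats.rankdata(values[obs, j], method="average")
        ranks[obs, j] = r
        col_pools.append((np.where(obs)[0], r))

    rp_obs = _row_rank_product(ranks)
    pattern = [tuple(np.where(np.isfinite(ranks[i]))[0]) for i in range(n_rows)]
    groups: dict[tuple, np.ndarray] = {}
    for pat in set(pattern):
        groups[pat] = np.array([i for i in range(n_rows) if pattern[i] == pat])

    rng = np.random.default_rng(seed)
    if exhaustive:
        from itertools import permutations as _perms, product as _product

        per_col = [list(_perms(r)) for _, r in col_pools]
        if np.prod([len(p) for p in per_col]) > 2_000_000:
            raise ValueError("exhaustive enumeration too large; use Monte Carlo")
        perm_iter = (
            [np.array(choice[j]) for j in range(n_cols)]
            for choice in _product(*per_col)
        )
    else:
        perm_iter = (
            [rng.permutation(r) for _, r in col_pools] for _ in range(n_perm)
        )

    exceed = np.zeros(n_rows)
    totals = np.zeros(n_rows)
    for shuffled in perm_iter:
        null = np.full_like(ranks, np.nan)
        for j, (rows, _) in enumerate(col_pools):
            null[rows, j] = shuffled[j]
        rp_null = _row_rank_product(null)
        for pat, idx in groups.items():
            pool = np.sort(rp_null[idx])
            exceed[idx] += np.searchsorted(pool, rp_obs[idx] + 1e-12, side="right")
            totals[idx] += pool.size
    p = exceed / totals

    out = pd.DataFrame(
        {
            "rp": rp_obs,
            "p_value": p,
            "adj_p": bh_adjust(p),
            "k": np.sum(np.isfinite(ranks), axis=1).astype(int),
            "direction": direction,
        },
        index=matrix.index,
    )
    return out.sort_values("rp")


def essential_depletion_test(
    log2fc: pd.Series, target_essential, background
) -> dict:
    """Two-sided two-sample KS test: are the miRNA's essential-gene
    targets more depleted than the remaining genes after miRNA elevation?

    ``log2fc`` maps gene -> perturbation log2 fold change.  The target
    and background sets must be disjoint and nonempty within the
    measured genes.  Also reports the directional median shift
    (targets minus background; negative = depleted).
    """
    t = set(target_essential)
    b = set(background)
    if t & b:
        raise ValueError("target and background sets overlap")
    a = log2fc.loc[log2fc.index.intersection(sorted(t))].dropna()
    c = log2fc.loc[log2fc.index.intersection(sorted(b))].dropna()
    if a.empty or c.empty:
        raise ValueError("both gene sets must be measured and nonempty")
    res = stats.ks_2samp(a.to_numpy(), c.to_numpy(), alternative="two-sided")
    return {
        "ks_statistic": float(res.statistic),
        "p_value": float(res.pvalue),
        "median_shift": float(a.median() - c.median()),
        "n_targets": int(a.size),
        "n_background": int(c.size),
    }
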