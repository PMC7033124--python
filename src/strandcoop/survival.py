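"""Four-strand miRNA signature survival analysis.

The signature is the per-patient mean of log2(normalized + 1) across
the four mature strands (two 5p/3p pairs); raw-scale averaging is
available behind a flag but lets one abundant strand dominate.
Patients are ranked by the signature and split into four near-equal
quartiles; overall survival of the lowest (Q1) vs highest (Q4) quartile
is compared by Kaplan-Meier curves and the log-rank test, with
follow-up truncated at a 10-year horizon (120 months).  The Cox
proportional-hazards model (Newton-Raphson on the partial likelihood,
Breslow ties by default, Efron optionally) supplies hazard ratios,
Wald tests and the multivariate adjustment for age, grade and stage.
Q4 is coded 1 and Q1 coded 0, so HR < 1 means high signature
expression is protective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

__all__ = [
    "signature_score",
    "quartile_stratify",
    "kaplan_meier",
    "logrank_test",
    "truncate_followup",
    "cox_fit",
    "compare_signatures",
    "CoxResult",
]


def signature_score(
    expression: pd.DataFrame, strands, log_scale: bool = True
) -> pd.Series:
    """Per-sample mean expression of the signature strands.

    ``expression`` is features x samples (normalized); every strand must
    be measured.  ``log_scale`` averages log2(x + 1) values.
    """
    missing = [s for s in strands if s not in expression.index]
    if missing:
        raise KeyError(f"signature strands not measured: {missing}")
    block = expression.loc[list(strands)]
    if log_scale:
        block = np.log2(block + 1.0)
    return block.mean(axis=0).rename("signature")


def quartile_stratify(scores: pd.Series) -> pd.Series:
    """Rank-based split into four near-equal quartiles Q1 (lowest) .. Q4.

    Ties are broken by stable patient-id order, so assignment is
    deterministic; group sizes follow the near-equal split of the sorted
    cohort (sizes differ by at most 1).
    """
    if len(scores) < 8:
        raise ValueError("need at least 8 patients for quartiles")
    if scores.nunique() == 1:
        warnings.warn("all-tied signature scores; quartiles assigned by id order")
    order = sorted(scores.index, key=lambda i: (scores.loc[i], str(i)))
    labels = pd.Series(index=scores.index, dtype=object)
    for q, chunk in enumerate(np.array_split(np.array(order, dtype=object), 4), start=1):
        labels.loc[chunk] = f"Q{q}"
    return labels


def truncate_followup(clinical: pd.DataFrame, horizon: float = 120.0) -> pd.DataFrame:
    """Administratively censor every record beyond ``horizon`` months."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    out = clinical.copy()
    over = out["time_months"] > horizon
    out.loc[over, "time_months"] = horizon
    out.loc[over, "event"] = 0
    return out


def kaplan_meier(time, event) -> tuple[pd.DataFrame, float]:
    """Product-limit survival estimate and median survival time.

    Returns a step table (one row per distinct event time: at-risk
    count, events, survival after the step) and the median — the first
    time at which S(t) <= 0.5, NaN if never reached.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if (time <= 0).any():
        raise ValueError("times must be positive")
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    rows = []
    s = 1.0
    n = time.size
    for t in np.unique(time[event == 1]):
        at_risk = int(np.sum(time >= t))
        d = int(np.sum((time == t) & (event == 1)))
        s *= 1.0 - d / at_risk
        rows.append({"time": float(t), "at_risk": at_risk, "events": d, "survival": s})
    km = pd.DataFrame(rows, columns=["time", "at_risk", "events", "survival"])
    median = float("nan")
    reached = km[km["survival"] <= 0.5]
    if not reached.empty:
        median = float(reached["time"].iloc[0])
    return km, median


def logrank_test(time_a, event_a, time_b, event_b) -> tuple[float, float]:
    """Two-group log-rank test: chi-square statistic (1 df) and p-value."""
    ta, ea = np.asarray(time_a, float), np.asarray(event_a, int)
    tb, eb = np.asarray(time_b, float), np.asarray(event_b, int)
    times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    o_minus_e = 0.0
    var = 0.0
    for t in times:
        n1 = np.sum(ta >= t)
        n2 = np.sum(tb >= t)
        d1 = np.sum((ta == t) & (ea == 1))
        d2 = np.sum((tb == t) & (eb == 1))
        n = n1 + n2
        d = d1 + d2
        if n < 2 or d == 0:
            continue
        e1 = d * n1 / n
        o_minus_e += d1 - e1
        var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if var <= 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


@dataclass
class CoxResult:
    covariate: str
    coef: float
    hr: float
    ci_low: float
    ci_high: float
    se: float
    wald_p: float
    converged: bool


def _cox_loglik(beta, x, time, event, ties):
    """Breslow/Efron partial log-likelihood with gradient and Hessian."""
    eta = x @ beta
    w = np.exp(eta)
    order = np.argsort(-time, kind="stable")  # descending time
    x_o, w_o, t_o, e_o = x[order], w[order], time[order], event[order]
    p = x.shape[1]
    ll, grad, hess = 0.0, np.zeros(p), np.zeros((p, p))
    s0, s1, s2 = 0.0, np.zeros(p), np.zeros((p, p))
    i = 0
    n = time.size
    while i < n:
        t = t_o[i]
        j = i
        while j < n and t_o[j] == t:
            s0 += w_o[j]
            s1 += w_o[j] * x_o[j]
            s2 += w_o[j] * np.outer(x_o[j], x_o[j])
            j += 1
        deaths = [k for k in range(i, j) if e_o[k] == 1]
        d = len(deaths)
        if d:
            xd = x_o[deaths]
            wd = w_o[deaths]
            ll += float(np.sum(xd @ beta))
            if ties == "breslow":
                for _ in range(d):
                    ll -= np.log(s0)
                    mu = s1 / s0
                    grad_term = mu
                    hess_term = s2 / s0 - np.outer(mu, mu)
                    grad -= grad_term
                    hess += hess_term
                grad += xd.sum(axis=0)
            else:  # efron
                wd_sum = wd.sum()
                xd_w = (wd[:, None] * xd).sum(axis=0)
                sd2 = np.einsum("i,ij,ik->jk", wd, xd, xd)
                for l in range(d):
                    f = l / d
                    den = s0 - f * wd_sum
                    num1 = s1 - f * xd_w
                    num2 = s2 - f * sd2
                    ll -= np.log(den)
                    mu = num1 / den
                    grad -= mu
                    hess += num2 / den - np.outer(mu, mu)
                grad += xd.sum(axis=0)
        i = j
    return ll, grad, hess  # third value is the observed information (-Hessian)


def cox_fit(
    covariates: pd.DataFrame,
    time,
    event,
    ties: str = "breslow",
    max_iter: int = 50,
    tol: float = 1e-9,
) -> list[CoxResult]:
    """Cox proportional-hazards fit by Newton-Raphson.

    ``covariates`` is patients x covariates (numeric, no NaN).  Returns
    one :class:`CoxResult` per covariate with HR = exp(beta), 95% CI
    exp(beta +/- 1.96 se) and the per-covariate Wald p.  Monotone
    likelihood or non-convergence within ``max_iter`` iterations is
    flagged (no estimate).
    """
    x = covariates.to_numpy(dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if np.isnan(x).any():
        raise ValueError("covariates contain NaN")
    n_events = int(event.sum())
    if n_events < 5 * x.shape[1]:
        warnings.warn(
            f"only {n_events} events for {x.shape[1]} covariates; "
            "estimates may be unstable"
        )
    # center covariates for numerical stability (does not change beta)
    center = x.mean(axis=0)
    xc = x - center
    p = x.shape[1]
    beta = np.zeros(p)
    converged = False
    ll_old = -np.inf
    for _ in range(max_iter):
        ll, grad, neg_hess = _cox_loglik(beta, xc, time, event, ties)
        try:
            step = np.linalg.solve(neg_hess, grad)
        except np.linalg.LinAlgError:
            break
        # step-halving if the likelihood does not improve
        factor = 1.0
        for _ in range(20):
            new = beta + factor * step
            ll_new, _, _ = _cox_loglik(new, xc, time, event, ties)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2
        beta = beta + factor * step
        if np.abs(beta).max() > 50:
            break  # monotone likelihood
        if abs(ll_new - ll_old) < tol:
            converged = True
            break
        ll_old = ll_new
    _, _, neg_hess = _cox_loglik(beta, xc, time, event, ties)
    try:
        cov = np.linalg.inv(neg_hess)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        converged = False
    results = []
    for j, name in enumerate(covariates.columns):
        # a runaway coefficient or exploded SE signals monotone likelihood
        ok = (
            converged
            and np.isfinite(se[j])
            and 0 < se[j] < 15
            and abs(beta[j]) < 15
        )
        if ok:
            z = beta[j] / se[j]
            wald = float(2 * stats.norm.sf(abs(z)))
            results.append(
                CoxResult(
                    covariate=str(name),
                    coef=float(beta[j]),
                    hr=float(np.exp(beta[j])),
                    ci_low=float(np.exp(beta[j] - 1.96 * se[j])),
                    ci_high=float(np.exp(beta[j] + 1.96 * se[j])),
                    se=float(se[j]),
                    wald_p=wald,
                    converged=True,
                )
            )
        else:
            results.append(
                CoxResult(
                    covariate=str(name),
                    coef=float("nan"), hr=float("nan"), ci_low=float("nan"),
                    ci_high=float("nan"), se=float("nan"), wald_p=float("nan"),
                    converged=False,
                )
            )
    return results


def compare_signatures(
    variant_pvalues: dict[str, dict[str, float]], reference: str
) -> float:
    """One-sided rank-sum test that the reference signature's survival
    associations are stronger than the pooled alternative variants.

    ``variant_pvalues`` maps variant name -> {cancer: log-rank p}; the
    comparison is on -log10 p across cancers (reference vs all others
    pooled).  Requires >= 3 cancers.
    """
    ref = variant_pvalues[reference]
    if len(ref) < 3:
        raise ValueError("need at least 3 cancers")
    ref_vals = -np.log10(np.clip(list(ref.values()), 1e-300, None))
    other_vals = -np.log10(
        np.clip(
            [
                p
                for name, d in variant_pvalues.items()
                if name != reference
                for p in d.values()
            ],
            1e-300,
            None,
        )
    )
    if other_vals.size == 0:
        raise ValueError("no alternative variants supplied")
    res = stats.mannwhitneyu(ref_vals, other_vals, alternative="greater")
    return float(res.pvalue)


def fdr_over_cancers(logrank_p_by_cancer: dict[str, float]) -> dict[str, float]:
    """BH adjustment of the per-cancer log-rank p-values."""
    cancers = sorted(logrank_p_by_cancer)
    adj = bh_adjust([logrank_p_by_cancer[c] for c in cancers])
    return dict(zip(cancers, adj))
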