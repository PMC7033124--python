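"""5p/3p strand pairing and pan-cancer concordance analysis.

A precursor hairpin yields two mature strands with different seed
sequences.  This module pairs the arms, contrasts within-pair expression
correlation against random cross-precursor pairs, pools per-(pair,
cancer) fold changes into a single concordance correlation, and applies
the pan-cancer selection rules: concordant dysregulation in at least
``min_cancers`` cancer types, and downregulation at least twice as
frequent as upregulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .datatypes import StrandPair, make_pair, parse_mature_id, ValidationError
from .diffexpr import CorrelationResult, spearman

__all__ = [
    "pair_strands",
    "background_pairs",
    "concordance_shift",
    "foldchange_concordance",
    "downregulation_bias",
    "pan_cancer_pairs",
    "PairDysregulation",
]


def pair_strands(mature_ids) -> tuple[list[StrandPair], list[str]]:
    """Group mature ids into 5p/3p pairs; return (pairs, singletons).

    A pair is formed only when both arms of a precursor are present.  A
    duplicated arm for one precursor is a data error.
    """
    by_precursor: dict[str, dict[str, str]] = {}
    for mid in mature_ids:
        m = parse_mature_id(mid)
        arms = by_precursor.setdefault(m.precursor_id, {})
        if m.arm in arms:
            raise ValidationError(f"duplicate {m.arm} arm for {m.precursor_id}")
        arms[m.arm] = m.mature_id
    pairs, singletons = [], []
    for precursor in sorted(by_precursor):
        arms = by_precursor[precursor]
        if len(arms) == 2:
            pairs.append(make_pair(precursor))
        else:
            singletons.extend(arms.values())
    return pairs, sorted(singletons)


def background_pairs(
    mature_ids, n_pairs: int, seed: int
) -> list[tuple[str, str]]:
    """Random cross-precursor strand pairs (the background of true pairs).

    Pairs are drawn uniformly without replacement from all unordered
    pairs of mature ids from *different* precursors; true 5p/3p pairs
    are excluded by construction.  If more pairs are requested than
    exist, sampling falls back to with-replacement with a warning.
    """
    ids = sorted(set(mature_ids))
    precursors = [parse_mature_id(m).precursor_id for m in ids]
    if len(set(precursors)) < 2:
        raise ValueError("need mature miRNA from at least 2 precursors")
    admissible = [
        (ids[i], ids[j])
        for i in range(len(ids))
        for j in range(i + 1, len(ids))
        if precursors[i] != precursors[j]
    ]
    rng = np.random.default_rng(seed)
    if n_pairs > len(admissible):
        warnings.warn(
            f"requested {n_pairs} background pairs but only "
            f"{len(admissible)} exist; sampling with replacement"
        )
        idx = rng.integers(0, len(admissible), size=n_pairs)
    else:
        idx = rng.choice(len(admissible), size=n_pairs, replace=False)
    return [admissible[i] for i in idx]


def concordance_shift(pair_correlations, background_correlations) -> float:
    """Two-sided Wilcoxon rank-sum p: true-pair vs background correlations.

    Uses the exact distribution for small samples (m + n <= 20 without
    ties) and the tie-corrected normal approximation otherwise.  All
    values tied across both samples gives p = 1.
    """
    a = np.asarray(pair_correlations, dtype=float)
    b = np.asarray(background_correlations, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 1.0
    method = "exact" if (a.size + b.size <= 20) else "asymptotic"
    try:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    except ValueError:  # exact method refuses ties
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def foldchange_concordance(pair_fold_table: pd.DataFrame) -> CorrelationResult:
    """Spearman correlation of 5p vs 3p log2 fold changes pooled over
    (pair, cancer) rows.

    ``pair_fold_table`` needs columns ``log2fc_5p`` and ``log2fc_3p``;
    each row is one strand pair in one cancer type, irrespective of
    whether the dysregulation was significant.
    """
    for col in ("log2fc_5p", "log2fc_3p"):
        if col not in pair_fold_table.columns:
            raise ValueError(f"missing column {col!r}")
    tab = pair_fold_table.dropna(subset=["log2fc_5p", "log2fc_3p"])
    if len(tab) < 4:
        raise ValueError("need at least 4 (pair, cancer) rows")
    return spearman(tab["log2fc_5p"].to_numpy(), tab["log2fc_3p"].to_numpy())


def downregulation_bias(
    calls, min_cancers: int = 5, bias_factor: float = 2.0
) -> tuple[int, int, bool]:
    """Apply the consistent-downregulation rule to one miRNA's calls.

    ``calls`` is the per-cancer call sequence (``up``/``down``/``ns``).
    Selection requires significant dysregulation in >= ``min_cancers``
    cancers and downregulation at least ``bias_factor`` times as
    frequent as upregulation.
    """
    calls = list(calls)
    n_down = sum(c == "down" for c in calls)
    n_up = sum(c == "up" for c in calls)
    selected = (n_down + n_up) >= min_cancers and n_down >= bias_factor * n_up
    return n_down, n_up, selected


@dataclass
class PairDysregulation:
    """Per-cancer dysregulation profile of one 5p/3p pair."""

    pair: StrandPair
    per_cancer: pd.DataFrame  # index cancer; log2fc_5p/3p, call_5p/3p
    min_cancers: int = 5

    @property
    def concordant_cancers(self) -> set[str]:
        """Cancers where both strands are significant with the same sign."""
        t = self.per_cancer
        both = (t["call_5p"] != "ns") & (t["call_5p"] == t["call_3p"])
        return set(t.index[both])

    @property
    def pan_cancer(self) -> bool:
        return len(self.concordant_cancers) >= self.min_cancers

    def direction_in(self, cancer: str) -> str:
        if cancer not in self.concordant_cancers:
            return "ns"
        return str(self.per_cancer.loc[cancer, "call_5p"])


def pan_cancer_pairs(
    dysregulations: list[PairDysregulation],
) -> tuple[list[PairDysregulation], pd.DataFrame]:
    """Select pan-cancer concordantly dysregulated pairs.

    Returns the selected pairs plus a heat-map-ready direction table
    (rows = precursors, columns = cancers, entries up/down/ns).
    """
    selected = [d for d in dysregulations if d.pan_cancer]
    if not dysregulations:
        return [], pd.DataFrame()
    cancers = sorted(set().union(*(set(d.per_cancer.index) for d in dysregulations)))
    table = pd.DataFrame(
        {
            c: [d.direction_in(c) for d in selected]
            for c in cancers
        },
        index=[d.pair.precursor_id for d in selected],
    )
    return selected, table


def build_pair_dysregulation(
    pair: StrandPair,
    de_by_cancer: dict[str, pd.DataFrame],
    min_cancers: int = 5,
) -> PairDysregulation:
    """Assemble a :class:`PairDysregulation` from per-cancer DE tables."""
    rows = {}
    id5, id3 = pair.mature_ids
    for cancer in sorted(de_by_cancer):
        de = de_by_cancer[cancer]
        if id5 not in de.index or id3 not in de.index:
            continue
        rows[cancer] = {
            "log2fc_5p": de.loc[id5, "log2fc"],
            "log2fc_3p": de.loc[id3, "log2fc"],
            "call_5p": de.loc[id5, "call"],
            "call_3p": de.loc[id3, "call"],
        }
    per_cancer = pd.DataFrame.from_dict(rows, orient="index")
    return PairDysregulation(pair=pair, per_cancer=per_cancer, min_cancers=min_cancers)
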