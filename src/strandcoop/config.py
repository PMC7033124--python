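"""Pipeline configuration: every printed cut-off in one place.

The defaults are the analysis constants of the framework: miRNA are
called dysregulated at >=1.5-fold with BH p < 0.05, mRNA at >=2-fold;
dependency-screen gene sets are called associated at FDR < 0.1 with
negative NES; pair-pathway coordination requires score < 0.5; recurrent
associations must appear in >=50% of the concordant cancer types; the
pan-cancer rule requires >=5 cancers; the down/up bias rule requires
downregulation at least twice as frequent as upregulation; features must
have normalized expression >=1 in >=50% of samples to be analyzed; the
correlation-null filter draws 10,000 random miRNA-gene pairs and demands
BH-adjusted Wilcoxon p < 1e-3; survival follow-up is truncated at 10
years (120 months).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml


@dataclass
class PipelineConfig:
    # differential expression
    mirna_fold_threshold: float = 1.5
    mrna_fold_threshold: float = 2.0
    alpha: float = 0.05
    pseudo_fold: float = 0.5  # pseudo-count for fold-change stabilization
    expr_min_value: float = 1.0
    expr_min_fraction: float = 0.5
    # dependency screen / GSEA
    nes_fdr: float = 0.1
    gsea_permutations: int = 1000
    gsea_exponent: float = 1.0
    min_set_size: int = 10
    max_set_size: int = 500
    balance_ratio: float = 1.5  # "<1.5-fold higher" strand-balance rule
    # strand concordance
    min_cancers: int = 5
    down_up_bias: float = 2.0
    background_multiplier: int = 10  # background pairs per true pair
    # pathway coordination
    coordination_cutoff: float = 0.5
    recurrence_cutoff: float = 0.5
    n_random_pairs: int = 10_000
    wilcoxon_alpha: float = 1e-3
    activation_quantile: float = 0.25  # top/bottom ssGSEA quartile split
    ssgsea_alpha: float = 0.25
    # regression / rank product
    rank_product_permutations: int = 10_000
    # survival
    horizon_months: float = 120.0
    # global
    seed: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "seed":
                continue
            value = getattr(self, f.name)
            if isinstance(value, (int, float)) and value <= 0:
                raise ValueError(f"config threshold {f.name} must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Stable hash identifying this configuration (embedded in reports)."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
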