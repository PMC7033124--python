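"""Shared domain types for the strand-cooperativity pipeline.

Matrices are always oriented features x samples and carried as pandas
DataFrames with string indices.  Sample identifiers are opaque; gene and
miRNA identifiers are case-sensitive and whitespace-trimmed (no aliasing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TUMOR = "tumor"
NORMAL = "normal"

ARM_SUFFIXES = ("-5p", "-3p")


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


@dataclass
class ExpressionStudy:
    """Paired tumor/normal expression matrices for one cancer type.

    Parameters
    ----------
    cancer_type:
        Label of the cohort (e.g. a TCGA-style abbreviation).
    raw_counts:
        Non-negative integer read counts, features x samples.
    normalized:
        Library-size normalized expression on the same index sets
        (RPM convention for miRNA, RPKM-style for mRNA).
    feature_kind:
        Either ``"miRNA"`` or ``"mRNA"``.
    sample_groups:
        Per-sample label, ``"tumor"`` or ``"normal"``.
    """

    cancer_type: str
    raw_counts: pd.DataFrame
    normalized: pd.DataFrame
    feature_kind: str
    sample_groups: pd.Series

    def __post_init__(self) -> None:
        if self.feature_kind not in ("miRNA", "mRNA"):
            raise ValidationError(f"unknown feature_kind {self.feature_kind!r}")
        if not self.raw_counts.index.equals(self.normalized.index):
            raise ValidationError("raw and normalized matrices disagree on features")
        if not self.raw_counts.columns.equals(self.normalized.columns):
            raise ValidationError("raw and normalized matrices disagree on samples")
        missing = set(self.raw_counts.columns) - set(self.sample_groups.index)
        if missing:
            raise ValidationError(
                f"samples absent from group metadata: {sorted(missing)}"
            )
        self.sample_groups = self.sample_groups.loc[self.raw_counts.columns]
        bad = set(self.sample_groups.unique()) - {TUMOR, NORMAL}
        if bad:
            raise ValidationError(f"unknown sample group labels: {sorted(bad)}")
        if (np.asarray(self.raw_counts) < 0).any():
            raise ValidationError("negative raw counts")

    @property
    def samples(self) -> pd.Index:
        return self.raw_counts.columns

    @property
    def features(self) -> pd.Index:
        return self.raw_counts.index

    @property
    def tumor_samples(self) -> pd.Index:
        return self.samples[self.sample_groups.loc[self.samples] == TUMOR]

    @property
    def normal_samples(self) -> pd.Index:
        return self.samples[self.sample_groups.loc[self.samples] == NORMAL]

    def subset_features(self, feature_ids) -> "ExpressionStudy":
        """Return a copy restricted to ``feature_ids`` (order preserved)."""
        idx = self.raw_counts.index.intersection(pd.Index(feature_ids))
        return ExpressionStudy(
            cancer_type=self.cancer_type,
            raw_counts=self.raw_counts.loc[idx],
            normalized=self.normalized.loc[idx],
            feature_kind=self.feature_kind,
            sample_groups=self.sample_groups.copy(),
        )


@dataclass(frozen=True)
class MatureMiRNA:
    """One mature miRNA strand (5p or 3p arm of a precursor hairpin)."""

    mature_id: str
    precursor_id: str
    arm: str

    def __post_init__(self) -> None:
        if self.arm not in ("5p", "3p"):
            raise ValidationError(f"arm must be 5p or 3p, got {self.arm!r}")
        if self.mature_id != f"{self.precursor_id}-{self.arm}":
            raise ValidationError(
                f"mature id {self.mature_id!r} does not parse to "
                f"{self.precursor_id!r} + -{self.arm}"
            )


def parse_mature_id(mature_id: str) -> MatureMiRNA:
    """Split a ``<precursor>-5p`` / ``<precursor>-3p`` identifier."""
    mature_id = mature_id.strip()
    for suffix in ARM_SUFFIXES:
        if mature_id.endswith(suffix):
            return MatureMiRNA(
                mature_id=mature_id,
                precursor_id=mature_id[: -len(suffix)],
                arm=suffix[1:],
            )
    raise ValidationError(f"{mature_id!r} carries no -5p/-3p arm suffix")


@dataclass(frozen=True)
class StrandPair:
    """The 5p and 3p mature strands of one precursor miRNA."""

    precursor_id: str
    mature_5p: MatureMiRNA
    mature_3p: MatureMiRNA

    def __post_init__(self) -> None:
        if not (
            self.mature_5p.precursor_id
            == self.mature_3p.precursor_id
            == self.precursor_id
        ):
            raise ValidationError("strand pair arms disagree on precursor")
        if self.mature_5p.arm == self.mature_3p.arm:
            raise ValidationError("strand pair needs one 5p and one 3p arm")

    @property
    def mature_ids(self) -> tuple[str, str]:
        return (self.mature_5p.mature_id, self.mature_3p.mature_id)


def make_pair(precursor_id: str) -> StrandPair:
    """Convenience constructor for ``<precursor>`` -> its 5p/3p pair."""
    return StrandPair(
        precursor_id=precursor_id,
        mature_5p=parse_mature_id(f"{precursor_id}-5p"),
        mature_3p=parse_mature_id(f"{precursor_id}-3p"),
    )


@dataclass
class TargetNetwork:
    """Directed miRNA -> gene edges with source provenance.

    ``edges`` columns: ``mature_id``, ``gene_id``, ``sources`` (a
    ``;``-joined sorted label set).  After cancer-specific filtering the
    annotated frame additionally carries ``rho``, ``adj_p`` and ``cancer``.
    """

    edges: pd.DataFrame

    REQUIRED = ("mature_id", "gene_id", "sources")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.edges.columns:
                raise ValidationError(f"edge table missing column {col!r}")
        if self.edges.duplicated(["mature_id", "gene_id"]).any():
            raise ValidationError("duplicate (mature_id, gene_id) edges")
        if (self.edges["sources"].astype(str).str.len() == 0).any():
            raise ValidationError("edge with empty source set")

    def targets_of(self, mature_id: str) -> set[str]:
        mask = self.edges["mature_id"] == mature_id
        return set(self.edges.loc[mask, "gene_id"])

    @property
    def mature_ids(self) -> set[str]:
        return set(self.edges["mature_id"])

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class DependencyMatrix:
    """Gene x cell-line viability/growth scores from a knockdown screen.

    Orientation is fixed at load time: a lower score means the line is
    more dependent on that gene.  ``platform`` is metadata only (``rnai``
    for DEMETER2-style, ``crispr`` for CERES-style); the two platforms
    are analyzed in parallel, never mixed.
    """

    scores: pd.DataFrame
    platform: str
    lineage: pd.Series  # cell line -> cancer_type

    def __post_init__(self) -> None:
        if self.platform not in ("rnai", "crispr"):
            raise ValidationError(f"unknown platform {self.platform!r}")
        missing = set(self.scores.columns) - set(self.lineage.index)
        if missing:
            raise ValidationError(f"cell lines without lineage: {sorted(missing)}")
        self.lineage = self.lineage.loc[self.scores.columns]

    def cell_lines_of(self, cancer_type: str) -> list[str]:
        return sorted(self.lineage.index[self.lineage == cancer_type])


@dataclass
class CovariateMatrices:
    """Per-gene methylation (beta values) and copy-number covariates.

    Columns must match the tumor samples of the mRNA expression study;
    rows align with gene identifiers.
    """

    methylation: pd.DataFrame
    copy_number: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.methylation.columns.equals(self.copy_number.columns):
            raise ValidationError("covariate matrices disagree on samples")


CLINICAL_COLUMNS = ("time_months", "event", "age", "grade", "stage")
"""Schema of a clinical table: patient_id index, survival time in months
(>0), event indicator (1 death / 0 censored), age in years, ordinal
histological grade (NaN allowed), and stage coded ``early``/``late``
(NaN allowed)."""


def validate_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Check and coerce a clinical table against :data:`CLINICAL_COLUMNS`."""
    for col in ("time_months", "event"):
        if col not in clinical.columns:
            raise ValidationError(f"clinical table missing column {col!r}")
    out = clinical.copy()
    out["time_months"] = out["time_months"].astype(float)
    out["event"] = out["event"].astype(int)
    if (out["time_months"] <= 0).any():
        raise ValidationError("survival times must be positive")
    if not out["event"].isin((0, 1)).all():
        raise ValidationError("event indicator must be 0 or 1")
    return out
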