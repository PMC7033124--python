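"""Readers and writers for the pipeline's plain-text formats.

All matrices travel as TSV with a header row and the row name in the
first column; pathway collections use GMT; stage reports use JSON.
Writers apply a canonical lexicographic row/column sort so outputs are
diffable; readers are inverse to writers on such canonical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ExpressionStudy, TargetNetwork, ValidationError


class LoadError(ValueError):
    """Raised when an input file violates its format contract."""


def read_matrix_tsv(path, dtype=float) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except ValueError as exc:
        raise LoadError(f"{path}: {exc}") from exc
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    try:
        df = df.astype(dtype)
    except ValueError as exc:
        # locate the first offending cell for the error message
        for i, row in enumerate(df.itertuples(index=False)):
            for j, value in enumerate(row):
                try:
                    dtype(value)
                except (TypeError, ValueError):
                    raise LoadError(
                        f"{path}: non-numeric value {value!r} at row "
                        f"{df.index[i]!r}, column {df.columns[j]!r}"
                    ) from exc
        raise LoadError(f"{path}: {exc}") from exc
    return df


def write_matrix_tsv(df: pd.DataFrame, path) -> None:
    out = df.sort_index(axis=0).sort_index(axis=1)
    out.to_csv(path, sep="\t")


def read_expression_study(
    counts_path, normalized_path, metadata_path, cancer_type: str, feature_kind: str
) -> ExpressionStudy:
    """Load an expression study from raw-count, normalized and metadata TSVs.

    The metadata TSV maps sample -> group (``tumor``/``normal``) in a
    column named ``group``.  Sample sets must agree across the three
    files; mismatches are reported by name.
    """
    raw = read_matrix_tsv(counts_path, dtype=float)
    if not np.allclose(raw.to_numpy(), np.round(raw.to_numpy())):
        raise LoadError(f"{counts_path}: raw counts must be integers")
    if (raw.to_numpy() < 0).any():
        raise LoadError(f"{counts_path}: negative counts")
    raw = raw.astype(np.int64)
    normalized = read_matrix_tsv(normalized_path, dtype=float)
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    if "group" not in meta.columns:
        raise LoadError(f"{metadata_path}: missing 'group' column")
    meta.index = meta.index.astype(str).str.strip()
    groups = meta["group"].astype(str).str.strip()
    extra = set(raw.columns) - set(groups.index)
    if extra:
        raise LoadError(f"samples absent from metadata: {sorted(extra)}")
    try:
        return ExpressionStudy(
            cancer_type=cancer_type,
            raw_counts=raw,
            normalized=normalized.loc[raw.index, raw.columns],
            feature_kind=feature_kind,
            sample_groups=groups,
        )
    except (KeyError, ValidationError) as exc:
        raise LoadError(str(exc)) from exc


def write_expression_study(study: ExpressionStudy, prefix) -> dict[str, Path]:
    """Write ``<prefix>.counts.tsv``, ``.norm.tsv`` and ``.meta.tsv``."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": prefix.with_suffix(".counts.tsv"),
        "normalized": prefix.with_suffix(".norm.tsv"),
        "metadata": prefix.with_suffix(".meta.tsv"),
    }
    write_matrix_tsv(study.raw_counts, paths["counts"])
    write_matrix_tsv(study.normalized, paths["normalized"])
    meta = pd.DataFrame(
        {"group": study.sample_groups.loc[sorted(study.samples)]}
    ).rename_axis("sample")
    meta.to_csv(paths["metadata"], sep="\t")
    return paths


def read_gmt(path) -> dict[str, set[str]]:
    """Parse a GMT pathway file into ``{name: gene set}``.

    Duplicate genes within a set are deduplicated; a line with fewer
    than three fields or an empty gene list is a parse error.
    """
    collection: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise LoadError(f"{path}:{lineno}: GMT line has <3 fields")
            name = parts[0].strip()
            genes = {g.strip() for g in parts[2:] if g.strip()}
            if not genes:
                raise LoadError(f"{path}:{lineno}: empty gene set {name!r}")
            collection[name] = genes
    return collection


def write_gmt(collection: dict[str, set[str]], path, descriptions=None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name in sorted(collection):
            desc = descriptions.get(name, "na")
            genes = "\t".join(sorted(collection[name]))
            fh.write(f"{name}\t{desc}\t{genes}\n")


def read_target_table(path, source: str) -> pd.DataFrame:
    """Read one (mature_id, gene_id) target-prediction table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("mature_id", "gene_id"):
        if col not in df.columns:
            raise LoadError(f"{path}: missing column {col!r}")
        df[col] = df[col].str.strip()
    df = df[["mature_id", "gene_id"]].drop_duplicates()
    df["source"] = source
    return df


def write_network(network: TargetNetwork, path) -> None:
    out = network.edges.sort_values(list(network.edges.columns)[:2])
    out.to_csv(path, sep="\t", index=False)


def read_network(path) -> TargetNetwork:
    edges = pd.read_csv(path, sep="\t", dtype={"mature_id": str, "gene_id": str})
    return TargetNetwork(edges=edges)


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip()
    return df


def write_json_report(payload: dict, path, *, config_hash: str, seed: int) -> None:
    """Write a stage report with the config hash and seed embedded.

    Serialization is sorted and ASCII-only so identical runs produce
    byte-identical files.
    """
    record = {"config_hash": config_hash, "seed": seed, **payload}
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(record, fh, sort_keys=True, indent=1, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialize {type(obj)}")
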