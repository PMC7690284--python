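"""Geneset scoring and dichotomization of expression cohorts.

Per-sample geneset Z-scores (mean of gene-wise standardized expression over
a set), median dichotomization into high/low tracks, combination of two
tracks into four groups, and signature–signature correlation. Standardization
uses the population SD (divisor n) by default, matching cohort-standardization
conventions of genomics visualization platforms; the divisor is exposed.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import survival as _survival
from .errors import ValidationError

__all__ = [
    "geneset_zscore",
    "dichotomize_by_median",
    "combine_tracks",
    "correlate_signatures",
    "read_expression_tsv",
    "read_gmt",
]


def geneset_zscore(matrix: pd.DataFrame, genes: list[str] | set[str], ddof: int = 0) -> pd.Series:
    """Per-sample geneset Z-score.

    ``matrix`` holds genes in rows and samples in columns (log-scale
    expression). Each gene is standardized across samples; the score is the
    mean standardized value over the geneset members present in the matrix.
    Constant genes (zero SD) are dropped with a warning.
    """
    if matrix.index.duplicated().any():
        raise ValidationError("expression matrix has duplicate gene ids")
    if matrix.shape[1] < 2:
        raise ValidationError("need at least 2 samples")
    present = [g for g in dict.fromkeys(genes) if g in matrix.index]
    if not present:
        raise ValidationError("no geneset genes found in the expression matrix")
    sub = matrix.loc[present].astype(float)
    sd = sub.std(axis=1, ddof=ddof)
    constant = sd == 0
    if constant.any():
        warnings.warn(f"dropped constant genes: {list(sub.index[constant])}")
        sub = sub.loc[~constant]
        sd = sd.loc[~constant]
        if sub.empty:
            raise ValidationError("all geneset genes are constant")
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    return z.mean(axis=0).rename("geneset_zscore")


def dichotomize_by_median(values: pd.Series) -> pd.Series:
    """Label each sample 'high' (value > median) or 'low' (ties go low)."""
    values = values.astype(float)
    if values.size < 2:
        raise ValidationError("need at least 2 samples to dichotomize")
    if values.nunique() < 2:
        raise ValidationError("all values equal; median split is degenerate")
    med = values.median()
    return pd.Series(np.where(values > med, "high", "low"), index=values.index, name="label")


def combine_tracks(labels_a: pd.Series, labels_b: pd.Series) -> pd.Series:
    """Cartesian 4-level grouping of two high/low tracks (e.g. 'high/low')."""
    if set(labels_a.index) != set(labels_b.index):
        raise ValidationError("track sample sets differ")
    labels_b = labels_b.reindex(labels_a.index)
    return (labels_a.astype(str) + "/" + labels_b.astype(str)).rename("group")


def correlate_signatures(scores_a, scores_b, method: str = "spearman") -> tuple[float, float]:
    """Correlate two per-sample signature scores; returns (coefficient, p)."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValidationError("need paired scores with n >= 3")
    if method == "spearman":
        return _survival.spearman_rank(a, b)
    if method == "pearson":
        if np.unique(a).size < 2 or np.unique(b).size < 2:
            raise ValidationError("correlation undefined for constant input")
        from scipy import stats

        r, p = stats.pearsonr(a, b)
        return float(r), float(p)
    raise ValidationError(f"unknown correlation method: {method!r}")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a genes-in-rows TSV expression matrix (first column = gene id)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read GMT genesets: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
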