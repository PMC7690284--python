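"""Molecular assay normalization and scoring.

Covers the quantitative post-processing of four bench assays:

* cytokine antibody arrays — spot intensities normalized to on-membrane
  positive/negative controls, fold induction between a hypoxic-supernatant
  (HPS) and a normoxic-supernatant (NPS) membrane with a one-tailed unpaired
  Student's t-test, and a candidate filter combining significance, fold,
  molecular-weight window (size-exclusion result) and qPCR confirmation;
* qPCR — ΔΔCt relative expression against a reference gene (B2M);
* flow cytometry — delta gMFI (geometric mean fluorescence minus isotype);
* transwell migration — subtraction of the no-attractant control curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import LayoutError, ValidationError

__all__ = [
    "CytokineRecord",
    "quantify_membrane",
    "fold_induction",
    "filter_candidates",
    "qpcr_relative_expression",
    "delta_gmfi",
    "correct_migration",
]


@dataclass(frozen=True)
class CytokineRecord:
    analyte: str
    normalized_nps: float
    normalized_hps: float
    fold_induction: float
    p_value: float
    mw_kda: float | None = None


def quantify_membrane(grid: pd.DataFrame) -> pd.DataFrame:
    """Control-normalize one membrane's spot intensities.

    ``grid`` columns: analyte, replicate, intensity, is_pos_ctrl,
    is_neg_ctrl. Each replicate intensity maps to
    (intensity − mean(neg controls)) / (mean(pos controls) − mean(neg
    controls)), clipped below at zero. Returns the per-replicate normalized
    table (analyte, replicate, normalized).
    """
    required = {"analyte", "replicate", "intensity", "is_pos_ctrl", "is_neg_ctrl"}
    missing = required - set(grid.columns)
    if missing:
        raise ValidationError(f"missing columns: {sorted(missing)}")
    pos = grid.loc[grid["is_pos_ctrl"].astype(bool), "intensity"]
    neg = grid.loc[grid["is_neg_ctrl"].astype(bool), "intensity"]
    if pos.empty or neg.empty:
        raise LayoutError("membrane needs at least one positive and one negative control spot")
    pos_mean, neg_mean = float(pos.mean()), float(neg.mean())
    if pos_mean <= neg_mean:
        raise ValidationError("positive control does not exceed negative control; membrane unusable")

    spots = grid.loc[~grid["is_pos_ctrl"].astype(bool) & ~grid["is_neg_ctrl"].astype(bool)].copy()
    spots["normalized"] = ((spots["intensity"] - neg_mean) / (pos_mean - neg_mean)).clip(lower=0.0)
    return spots[["analyte", "replicate", "normalized"]].reset_index(drop=True)


def fold_induction(
    hps: pd.DataFrame,
    nps: pd.DataFrame,
    mw_kda: dict[str, float] | None = None,
) -> list[CytokineRecord]:
    """Fold induction HPS/NPS per analyte with a one-tailed unpaired t-test.

    Inputs are per-replicate normalized tables from :func:`quantify_membrane`.
    The t-test is the classic pooled-variance unpaired Student's test with
    alternative HPS > NPS. Analytes with zero NPS normalized mean get
    fold = inf and are flagged via a warning.
    """
    for df, name in ((hps, "hps"), (nps, "nps")):
        if not {"analyte", "normalized"} <= set(df.columns):
            raise ValidationError(f"{name} table must have analyte and normalized columns")
    a_h = set(hps["analyte"])
    a_n = set(nps["analyte"])
    if a_h != a_n:
        raise ValidationError(f"analyte sets differ between membranes: {sorted(a_h ^ a_n)}")

    records = []
    for analyte in sorted(a_h):
        h = hps.loc[hps["analyte"] == analyte, "normalized"].to_numpy(dtype=float)
        n = nps.loc[nps["analyte"] == analyte, "normalized"].to_numpy(dtype=float)
        mean_h, mean_n = float(h.mean()), float(n.mean())
        if mean_n == 0.0:
            warnings.warn(f"{analyte}: zero NPS normalized intensity; fold undefined")
            fold = float("inf")
        else:
            fold = mean_h / mean_n
        if h.size >= 2 and n.size >= 2 and (np.ptp(h) > 0 or np.ptp(n) > 0):
            p = float(stats.ttest_ind(h, n, equal_var=True, alternative="greater").pvalue)
        else:
            p = 1.0 if mean_h <= mean_n else 0.5  # degenerate: no within-group spread
        records.append(
            CytokineRecord(
                analyte=analyte,
                normalized_nps=mean_n,
                normalized_hps=mean_h,
                fold_induction=fold,
                p_value=p,
                mw_kda=None if mw_kda is None else mw_kda.get(analyte),
            )
        )
    return records


def filter_candidates(
    records: list[CytokineRecord],
    qpcr_upregulated: set[str],
    mw_min: float = 30.0,
    mw_max: float = 100.0,
    alpha: float = 0.05,
) -> list[str]:
    """Stepwise candidate selection.

    Retains analytes that are significantly induced (p < alpha, fold > 1),
    fall inside the molecular-weight window [mw_min, mw_max] kDa established
    by size exclusion (endpoints inclusive), and are confirmed upregulated at
    the mRNA level. Analytes without a MW annotation are excluded with a
    warning.
    """
    retained = []
    for rec in records:
        if rec.mw_kda is None:
            warnings.warn(f"{rec.analyte}: no molecular weight annotation; excluded")
            continue
        if (
            rec.p_value < alpha
            and rec.fold_induction > 1.0
            and mw_min <= rec.mw_kda <= mw_max
            and rec.analyte in qpcr_upregulated
        ):
            retained.append(rec.analyte)
    return retained


def qpcr_relative_expression(records: pd.DataFrame, control_label: str = "control") -> pd.Series:
    """Per-gene fold change by the ΔΔCt method.

    ``records`` columns: sample, gene, ct_target, ct_reference, condition.
    ΔCt = Ct_target − Ct_reference per sample; ΔΔCt = mean ΔCt(treated) −
    mean ΔCt(control); fold = 2^(−ΔΔCt). Samples missing the reference Ct
    are dropped with a warning.
    """
    required = {"sample", "gene", "ct_target", "ct_reference", "condition"}
    missing = required - set(records.columns)
    if missing:
        raise ValidationError(f"missing columns: {sorted(missing)}")
    df = records.copy()
    bad = df["ct_reference"].isna() | df["ct_target"].isna()
    if bad.any():
        warnings.warn(f"dropped {int(bad.sum())} samples without target/reference Ct")
        df = df.loc[~bad]
    df["dct"] = df["ct_target"] - df["ct_reference"]

    folds = {}
    for gene, sub in df.groupby("gene"):
        is_ctrl = sub["condition"] == control_label
        if not is_ctrl.any() or is_ctrl.all():
            raise ValidationError(f"{gene}: need both treated and {control_label!r} samples")
        ddct = sub.loc[~is_ctrl, "dct"].mean() - sub.loc[is_ctrl, "dct"].mean()
        folds[gene] = 2.0 ** (-ddct)
    return pd.Series(folds, name="fold_change").sort_index()


def delta_gmfi(stained, isotype) -> float:
    """gMFI(stained) − gMFI(isotype), gMFI being the geometric mean."""
    stained = np.asarray(stained, dtype=float)
    isotype = np.asarray(isotype, dtype=float)
    if stained.size == 0 or isotype.size == 0:
        raise ValidationError("both samples must be non-empty")
    if (stained <= 0).any() or (isotype <= 0).any():
        raise ValidationError("geometric mean requires strictly positive fluorescence values")
    return float(np.exp(np.mean(np.log(stained))) - np.exp(np.mean(np.log(isotype))))


def correct_migration(
    timepoints, with_attractant, without_attractant
) -> pd.DataFrame:
    """Subtract the no-attractant control from a migration curve."""
    t = np.asarray(timepoints, dtype=float)
    w = np.asarray(with_attractant, dtype=float)
    wo = np.asarray(without_attractant, dtype=float)
    if not (t.shape == w.shape == wo.shape):
        raise ValidationError("time grids and signal series must have equal length")
    return pd.DataFrame({"time_min": t, "corrected_signal": w - wo})
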