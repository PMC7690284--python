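"""Survival and rank statistics.

Kaplan–Meier product-limit estimation, the two-group log-rank test, a
maximally selected log-rank cut-point scan for continuous biomarkers, and
the Mann–Whitney and Spearman tests used alongside them.

The cut-point scan deliberately applies no multiple-testing correction: it
reports the scan-minimized p-value as found, flagged as exploratory, which
matches how population-based "best discriminating" cut-offs are typically
derived; validation in an independent cohort is the user's responsibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lifelines import KaplanMeierFitter
from scipy import stats

from .errors import ValidationError

__all__ = [
    "KMCurve",
    "LogRankResult",
    "CutoffScan",
    "kaplan_meier",
    "log_rank",
    "optimal_cutoff_scan",
    "mann_whitney_two_tailed",
    "spearman_rank",
]


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate.

    ``median_survival`` is the smallest event time with S(t) <= 0.5 and is
    ``None`` when the curve never reaches 0.5 ("not reached").
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median_survival: float | None

    @property
    def median_reached(self) -> bool:
        return self.median_survival is not None


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    p_value: float
    observed: tuple[float, float]
    expected: tuple[float, float]


@dataclass(frozen=True)
class CutoffScan:
    """Result of a maximally selected log-rank cut-point search.

    ``best_cutoff_interval`` is the full range of thresholds attaining the
    minimal p-value: the union, over all best candidates, of the gaps between
    the adjacent data values they separate. The minimized p-value is
    exploratory (no correction for the scan).
    """

    candidates: np.ndarray
    p_values: np.ndarray
    best_cutoff: float
    best_p: float
    best_cutoff_interval: tuple[float, float]
    group_sizes: tuple[int, int]
    exploratory: bool = field(default=True)


def _as_cohort(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    if time.shape != event.shape or time.ndim != 1:
        raise ValidationError("time and event must be equal-length 1-D vectors")
    if time.size == 0:
        raise ValidationError("empty cohort")
    if not np.all(np.isfinite(time)) or np.any(time <= 0):
        raise ValidationError("times must be finite and positive")
    if not np.isin(event, (0, 1)).all():
        raise ValidationError("event flags must be 0 or 1")
    return time, event


def kaplan_meier(time, event) -> KMCurve:
    """Kaplan–Meier estimate S(t) = Π_{t_i<=t} (1 − d_i/n_i)."""
    time, event = _as_cohort(time, event)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    survival = sf.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    med = kmf.median_survival_time_
    median = None if np.isinf(med) else float(med)
    return KMCurve(times=times, survival=survival, at_risk=at_risk, median_survival=median)


def log_rank(time, event, groups) -> LogRankResult:
    """Two-group log-rank test.

    At each distinct event time the risk sets are pooled; group-1 expected
    events are d_j·n1_j/n_j with hypergeometric variance, and the statistic
    (ΣO − ΣE)²/ΣV is referred to chi-square with 1 df.
    """
    time, event = _as_cohort(time, event)
    groups = np.asarray(groups)
    if groups.shape != time.shape:
        raise ValidationError("group labels must align with the cohort")
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValidationError(f"log-rank requires exactly 2 groups, got {labels.size}")
    if event.sum() == 0:
        raise ValidationError("log-rank requires at least one event")
    in1 = groups == labels[0]

    order = np.argsort(time, kind="stable")
    t, e, g1 = time[order], event[order], in1[order]
    ev = e == 1
    event_times = np.unique(t[ev])

    # at-risk counts just before each event time (right-continuous risk sets)
    left = np.searchsorted(t, event_times, side="left")
    cum_g1 = np.concatenate([[0], np.cumsum(g1)])
    n_at = (t.size - left).astype(float)
    n1_at = (g1.sum() - cum_g1[left]).astype(float)
    t_ev, t_ev1 = t[ev], t[ev & g1]
    d_at = (
        np.searchsorted(t_ev, event_times, side="right")
        - np.searchsorted(t_ev, event_times, side="left")
    ).astype(float)
    d1_at = (
        np.searchsorted(t_ev1, event_times, side="right")
        - np.searchsorted(t_ev1, event_times, side="left")
    ).astype(float)

    expected1 = d_at * n1_at / n_at
    with np.errstate(divide="ignore", invalid="ignore"):
        var = d_at * (n1_at / n_at) * (1 - n1_at / n_at) * (n_at - d_at) / (n_at - 1)
    var = np.where(n_at > 1, var, 0.0)

    o1, e1, v = d1_at.sum(), expected1.sum(), var.sum()
    o2 = d_at.sum() - o1
    e2 = d_at.sum() - e1
    if v <= 0:
        raise ValidationError("log-rank variance is zero (degenerate risk sets)")
    chi2 = (o1 - e1) ** 2 / v
    return LogRankResult(
        statistic=float(chi2),
        p_value=float(stats.chi2.sf(chi2, df=1)),
        observed=(float(o1), float(o2)),
        expected=(float(e1), float(e2)),
    )


def optimal_cutoff_scan(
    time, event, biomarker, min_group_fraction: float = 0.1
) -> CutoffScan:
    """Maximally selected log-rank cut-point search.

    Candidate cut-offs are the midpoints between consecutive sorted unique
    biomarker values whose split leaves both groups at least
    ``min_group_fraction`` of the cohort. The scan reports the minimal
    log-rank p, a representative best cut-off (lowest attaining candidate),
    and the full threshold interval attaining the minimum.
    """
    time, event = _as_cohort(time, event)
    biomarker = np.asarray(biomarker, dtype=float)
    if biomarker.shape != time.shape:
        raise ValidationError("biomarker must align with the cohort")
    uniq = np.unique(biomarker)
    if uniq.size < 2:
        raise ValidationError("biomarker is constant; no cut-off exists")

    n = time.size
    min_count = min_group_fraction * n
    candidates, pvals, sizes = [], [], []
    for lo, hi in zip(uniq[:-1], uniq[1:]):
        cut = 0.5 * (lo + hi)
        high = biomarker > cut
        n_high = int(high.sum())
        if n_high < min_count or (n - n_high) < min_count:
            continue
        try:
            res = log_rank(time, event, high)
        except ValidationError:
            continue
        candidates.append(cut)
        pvals.append(res.p_value)
        sizes.append((n - n_high, n_high))
    if not candidates:
        raise ValidationError("no feasible cut-off candidates")

    candidates = np.asarray(candidates)
    pvals = np.asarray(pvals)
    best_p = float(pvals.min())
    attain = np.isclose(pvals, best_p, rtol=1e-12, atol=0.0)
    best_idx = int(np.argmax(attain))  # first (lowest) attaining candidate
    # threshold interval: any cut-off in (lo, hi] induces the same split as
    # the midpoint candidate between lo and hi; take the union over ties.
    lows, highs = [], []
    for cut in candidates[attain]:
        lows.append(uniq[uniq <= cut].max())
        highs.append(uniq[uniq > cut].min())
    return CutoffScan(
        candidates=candidates,
        p_values=pvals,
        best_cutoff=float(candidates[best_idx]),
        best_p=best_p,
        best_cutoff_interval=(float(min(lows)), float(max(highs))),
        group_sizes=sizes[best_idx],
    )


def mann_whitney_two_tailed(x, y) -> tuple[float, float]:
    """Two-tailed Mann–Whitney U test.

    Exact p by enumeration for small untied samples (n1+n2 <= 12); normal
    approximation with tie correction otherwise. Returns (U of x, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    small = x.size + y.size <= 12
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def spearman_rank(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with t-based p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need paired samples with n >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValidationError("correlation undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
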