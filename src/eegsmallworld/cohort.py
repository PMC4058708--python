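"""Subject-level aggregation and cohort outcome statistics.

Per-epoch network metrics are averaged into per-subject summaries over the
0-24, 0-48 and 0-72 h windows (subjects whose registration stopped early
contribute the epochs they have).  Group contrasts between non-survivors
(CPC = 5) and survivors (CPC < 5) use pooled-variance two-sample t-tests
per metric, a Spearman correlation against the CPC score, and a composite
sum-of-centered-ranks score compared with the Wilcoxon rank-sum test.  ROC
analysis reports the maximum sensitivity attainable at 100% specificity.

The composite score ranks each subject on network size, number of
connections, relative path length, and relative clustering (the latter with
inverted orientation so that all four components point toward survival),
centres each rank column at zero and sums the four centred ranks; scores
therefore sum to zero over the cohort.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _st
from sklearn.metrics import roc_auc_score, roc_curve

from .network import NetworkMetrics

#: metrics reported in cohort contrasts (SWI_raw kept out of the tables)
REPORT_METRICS = ("network_size", "n_connections", "L_rel", "C_rel", "SWI")

#: composite components and their rank orientation (+1: larger value ->
#: larger rank; -1: inverted).  All four point toward survival.
DEFAULT_RANK_ORIENTATION: dict[str, int] = {
    "network_size": +1,
    "n_connections": +1,
    "L_rel": +1,
    "C_rel": -1,
}

WINDOWS_H = (24.0, 48.0, 72.0)


class StatisticalError(ValueError):
    """A contrast cannot be computed (group too small or single-class)."""


@dataclass
class SubjectRecord:
    """Outcome labels plus the metric timeline of one subject."""

    subject_id: str
    cpc: int
    ssep_status: str
    visual_eeg: str
    metric_timeline: dict[float, NetworkMetrics] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cpc not in (1, 2, 3, 4, 5):
            raise ValueError("cpc must be 1..5")

    @property
    def survivor(self) -> bool:
        return self.cpc < 5


@dataclass
class ComparisonResult:
    """Two-group contrast of one per-subject quantity."""

    group_a: str
    group_b: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    statistic: float
    p_value: float
    test: str = "t"


def period_average(record: SubjectRecord, window_h: float) -> dict[str, float]:
    """Per-metric mean over the subject's epochs starting before ``window_h``.

    NaN metrics are skipped per metric; a subject with no epoch in the
    window yields an all-NaN entry (missing from that window's tables).
    """
    chunks = [
        m.as_dict()
        for hour, m in record.metric_timeline.items()
        if 0.0 <= hour < window_h
    ]
    names = [f for f in NetworkMetrics.__dataclass_fields__]
    if not chunks:
        return {name: np.nan for name in names}
    out = {}
    for name in names:
        vals = np.array([c[name] for c in chunks], dtype=float)
        finite = vals[np.isfinite(vals)]
        out[name] = float(finite.mean()) if finite.size else np.nan
    return out


def period_table(records: list[SubjectRecord], window_h: float) -> pd.DataFrame:
    """Per-subject period summaries plus outcome labels for one window."""
    rows = []
    for rec in records:
        row = period_average(rec, window_h)
        if all(not np.isfinite(v) for v in row.values()):
            continue  # no registration inside the window
        row.update(
            subject_id=rec.subject_id,
            cpc=rec.cpc,
            survivor=rec.survivor,
            ssep_status=rec.ssep_status,
            visual_eeg=rec.visual_eeg,
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")


def compare_groups(
    values: np.ndarray,
    in_group_a: np.ndarray,
    group_a: str = "non_survivor",
    group_b: str = "survivor",
) -> ComparisonResult:
    """Pooled-variance two-sample t-test of one per-subject metric.

    NaN values are dropped; each group must retain at least two subjects.
    """
    values = np.asarray(values, dtype=float)
    in_group_a = np.asarray(in_group_a, dtype=bool)
    keep = np.isfinite(values)
    a = values[keep & in_group_a]
    b = values[keep & ~in_group_a]
    if len(a) < 2 or len(b) < 2:
        raise StatisticalError(
            f"need >= 2 subjects per group, got {len(a)} vs {len(b)}"
        )
    t, p = _st.ttest_ind(a, b, equal_var=True)
    return ComparisonResult(
        group_a, group_b,
        float(a.mean()), float(a.std(ddof=1)), len(a),
        float(b.mean()), float(b.std(ddof=1)), len(b),
        float(t), float(p), test="t",
    )


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho (mid-ranks)."""
    rx = _st.rankdata(x)
    ry = _st.rankdata(y)
    n = len(rx)
    perms = np.array(list(itertools.permutations(range(n))))
    ry_perm = ry[perms]  # (n!, n)
    rx_c = rx - rx.mean()
    ry_c = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum(axis=1))
    rho = (ry_c @ rx_c) / denom
    return float(np.mean(np.abs(rho) >= abs(rho_obs) - 1e-12))


def correlate_cpc(
    values: np.ndarray, cpc: np.ndarray, exact_max_n: int = 8
) -> tuple[float, float]:
    """Spearman rank correlation between a metric and the CPC score.

    Mid-ranks handle ties.  For n <= ``exact_max_n`` the two-sided p-value
    is computed by exhaustive permutation; above that the tie-corrected
    large-sample approximation is used.  Constant input yields (nan, nan).
    """
    values = np.asarray(values, dtype=float)
    cpc = np.asarray(cpc, dtype=float)
    keep = np.isfinite(values) & np.isfinite(cpc)
    x, y = values[keep], cpc[keep]
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return (math.nan, math.nan)
    rho, p = _st.spearmanr(x, y)
    if len(x) <= exact_max_n:
        p = _exact_spearman_p(x, y, rho)
    return (float(rho), float(p))


def sum_of_ranks(
    table: pd.DataFrame,
    in_group_a: np.ndarray | None = None,
    orientation: dict[str, int] | None = None,
    group_a: str = "non_survivor",
    group_b: str = "survivor",
) -> tuple[pd.Series, ComparisonResult]:
    """Composite sum-of-centered-ranks score and its Wilcoxon contrast.

    Each component metric is ranked across the whole cohort with mid-ranks
    (after applying its orientation sign), the ranks are centred by
    subtracting the column mean, and the per-subject score is the sum of
    the four centred ranks (hence scores sum to 0).  Subjects missing any
    component are excluded.  Groups are compared with the Wilcoxon rank-sum
    test on the scores (exact null distribution when there are no ties).
    """
    orientation = orientation or DEFAULT_RANK_ORIENTATION
    cols = list(orientation)
    sub = table[cols].astype(float)
    keep = np.isfinite(sub.values).all(axis=1)
    sub = sub.loc[keep]
    if len(sub) < 2:
        raise StatisticalError("fewer than two subjects with complete metrics")

    centred = np.zeros(len(sub))
    for col, sign in orientation.items():
        ranks = _st.rankdata(sign * sub[col].values)
        centred += ranks - ranks.mean()
    scores = pd.Series(centred, index=sub.index, name="sum_of_ranks")

    result = None
    if in_group_a is not None:
        mask = pd.Series(np.asarray(in_group_a, dtype=bool), index=table.index)
        mask = mask.loc[scores.index]
        a = scores[mask].values
        b = scores[~mask].values
        if len(a) < 2 or len(b) < 2:
            raise StatisticalError("need >= 2 subjects per group for rank test")
        ties = len(np.unique(scores.values)) < len(scores)
        method = "asymptotic" if ties else "exact"
        res = _st.mannwhitneyu(a, b, alternative="two-sided", method=method)
        result = ComparisonResult(
            group_a, group_b,
            float(a.mean()), float(a.std(ddof=1)), len(a),
            float(b.mean()), float(b.std(ddof=1)), len(b),
            float(res.statistic), float(res.pvalue), test="wilcoxon",
        )
    return scores, result


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    sensitivity_at_full_specificity: float


def roc_analysis(scores: np.ndarray, poor_outcome: np.ndarray) -> RocResult:
    """ROC of a per-subject score against the poor-outcome label.

    ``scores`` must be oriented so that larger values indicate poorer
    expected outcome.  Reports the full curve, the area under it, and the
    maximum sensitivity among thresholds producing zero false positives.
    """
    scores = np.asarray(scores, dtype=float)
    poor = np.asarray(poor_outcome, dtype=bool)
    keep = np.isfinite(scores)
    scores, poor = scores[keep], poor[keep]
    if poor.all() or (~poor).all():
        raise StatisticalError("ROC needs both outcome classes")
    fpr, tpr, thr = roc_curve(poor, scores)
    auc = float(roc_auc_score(poor, scores))
    at_full_spec = tpr[fpr == 0]
    sens = float(at_full_spec.max()) if at_full_spec.size else 0.0
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc,
                     sensitivity_at_full_specificity=sens)


def subgroup_compare(
    table: pd.DataFrame,
    grouping: str,
    orientation: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-metric contrasts for the SSEP or visual-EEG subgrouping.

    ``grouping='ssep_status'`` contrasts bilateral-absent against present
    SSEP.  ``grouping='visual_eeg'`` pools iso-electric with low-voltage
    and contrasts them against diffuse slowing; burst suppression and
    'other' records are excluded from that contrast.
    """
    if grouping == "ssep_status":
        sel = table
        in_a = (sel["ssep_status"] == "bilateral_absent").values
        names = ("bilateral_absent", "present")
    elif grouping == "visual_eeg":
        sel = table[table["visual_eeg"].isin(
            ["iso_electric", "low_voltage", "diffuse_slowing"]
        )]
        in_a = sel["visual_eeg"].isin(["iso_electric", "low_voltage"]).values
        names = ("iso_electric/low_voltage", "diffuse_slowing")
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    if in_a.sum() == 0 or (~in_a).sum() == 0:
        raise StatisticalError(f"empty group under {grouping}")

    rows = []
    for metric in REPORT_METRICS:
        r = compare_groups(sel[metric].values, in_a, *names)
        rows.append(_comparison_row(metric, r))
    _, comp = sum_of_ranks(sel, in_a, orientation, *names)
    rows.append(_comparison_row("sum_of_ranks", comp))
    return pd.DataFrame(rows).set_index("metric")


def _comparison_row(metric: str, r: ComparisonResult) -> dict:
    return {
        "metric": metric,
        "group_a": r.group_a, "mean_a": r.mean_a, "sd_a": r.sd_a, "n_a": r.n_a,
        "group_b": r.group_b, "mean_b": r.mean_b, "sd_b": r.sd_b, "n_b": r.n_b,
        "statistic": r.statistic, "p_value": r.p_value, "test": r.test,
    }


def outcome_report(
    records: list[SubjectRecord],
    windows_h: tuple[float, ...] = WINDOWS_H,
    orientation: dict[str, int] | None = None,
) -> dict[float, dict]:
    """Survivor/non-survivor contrasts for each aggregation window.

    For every window this returns the per-subject summary table, the
    per-metric t-contrasts, Spearman correlations with CPC, the composite
    sum-of-ranks contrast, and the ROC of the (negated) composite score for
    predicting poor outcome.
    """
    out: dict[float, dict] = {}
    for window in windows_h:
        table = period_table(records, window)
        non_surv = (~table["survivor"].astype(bool)).values
        contrasts = []
        correlations = []
        for metric in REPORT_METRICS:
            contrasts.append(
                _comparison_row(metric, compare_groups(table[metric].values, non_surv))
            )
            rho, p = correlate_cpc(table[metric].values, table["cpc"].values)
            correlations.append({"metric": metric, "rho": rho, "p_value": p})
        scores, comp = sum_of_ranks(table, non_surv, orientation)
        contrasts.append(_comparison_row("sum_of_ranks", comp))
        rho, p = correlate_cpc(scores.values, table.loc[scores.index, "cpc"].values)
        correlations.append({"metric": "sum_of_ranks", "rho": rho, "p_value": p})
        # low composite score predicts poor outcome; negate for ROC orientation
        roc = roc_analysis(
            -scores.values, ~table.loc[scores.index, "survivor"].astype(bool).values
        )
        out[window] = {
            "table": table,
            "contrasts": pd.DataFrame(contrasts).set_index("metric"),
            "correlations": pd.DataFrame(correlations).set_index("metric"),
            "scores": scores,
            "roc": roc,
        }
    return out
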