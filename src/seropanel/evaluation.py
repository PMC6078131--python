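"""Diagnostic and statistical evaluation: ROC/AUC, group tests, concordance.

The AUC is the Mann–Whitney concordance probability: the chance that a random
patient scores above a random control, with ties counted one half. The ROC
curve is built by sweeping a threshold over the unique scores.

Group comparisons follow the nonparametric toolkit used in serology studies:
two-sided Mann–Whitney rank-sum for two groups (exact enumeration when the
combined sample size is at most 20 and there are no ties, otherwise a normal
approximation with tie and continuity corrections — the variant used is
recorded in the result), Kruskal–Wallis for three or more groups, Spearman
rank correlation for paired continuous measures, and Shapiro–Wilk as a
normality screen reported for information only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import AnalysisError


@dataclass
class ROCResult:
    """ROC points (sorted by FPR), the AUC, and one operating point."""

    points: pd.DataFrame  # columns fpr, tpr, threshold
    auc: float
    threshold: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise AnalysisError(f"AUC out of range: {self.auc}")
        fpr = self.points["fpr"].to_numpy()
        if fpr[0] != 0.0 or fpr[-1] != 1.0 or (np.diff(fpr) < 0).any():
            raise AnalysisError("ROC points must run from (0,0) to (1,1) sorted by FPR")


def roc_auc(scores: pd.Series, labels: pd.Series, threshold: float | None = None) -> ROCResult:
    """ROC curve and AUC of patient-vs-control scores.

    ``labels`` are 'patient'/'control'. The AUC equals the Mann–Whitney
    concordance probability with ties counted ½. If ``threshold`` is given,
    the operating point uses the rule score ≥ threshold ⇒ patient.
    """
    labels = labels.reindex(scores.index)
    y = (labels.to_numpy() == "patient").astype(int)
    s = scores.to_numpy(float)
    if not np.isfinite(s).all():
        raise AnalysisError("scores must be finite")
    if y.sum() == 0 or y.sum() == len(y):
        raise AnalysisError("both classes must be present for ROC analysis")

    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})

    # AUC as the pairwise concordance probability (trapezoid over the sweep
    # curve equals this; computed via the rank formula for robustness to ties)
    ranks = stats.rankdata(s)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    auc = float(u / (n1 * n0))

    sens = spec = None
    if threshold is not None:
        pred = s >= threshold
        sens = float(pred[y == 1].mean())
        spec = float((~pred)[y == 0].mean())
    return ROCResult(points=points, auc=auc, threshold=threshold, sensitivity=sens, specificity=spec)


@dataclass
class TestResult:
    """One statistical test: name, statistic, p, variant, group summaries."""

    test: str
    statistic: float
    p_value: float
    variant: str = ""
    group_summary: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise AnalysisError(f"p-value out of range: {self.p_value}")


def _group_summary(values: pd.Series, grouping: pd.Series) -> pd.DataFrame:
    rows = {}
    for g, grp in values.groupby(grouping):
        v = grp.to_numpy(float)
        rows[g] = {
            "n": int(len(v)),
            "median": float(np.median(v)),
            "q25": float(np.percentile(v, 25)),
            "q75": float(np.percentile(v, 75)),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def compare_groups(
    values: pd.Series,
    grouping: pd.Series,
    test: str = "rank-sum",
    other: pd.Series | None = None,
) -> TestResult:
    """Nonparametric group comparison / correlation / normality screen.

    ``test``: 'rank-sum' (two groups), 'kruskal' (≥2 groups), 'spearman'
    (paired with ``other``; ``grouping`` is ignored), or 'shapiro'
    (normality screen on ``values``). All p-values are two-sided.
    """
    if test == "spearman":
        if other is None:
            raise AnalysisError("spearman requires the paired vector `other`")
        a = values.to_numpy(float)
        b = other.reindex(values.index).to_numpy(float)
        if len(a) != len(b) or np.isnan(b).any():
            raise AnalysisError("spearman requires aligned paired vectors")
        res = stats.spearmanr(a, b)
        return TestResult("spearman", float(res.statistic), float(res.pvalue), variant="asymptotic")

    if test == "shapiro":
        res = stats.shapiro(values.to_numpy(float))
        return TestResult("shapiro", float(res.statistic), float(res.pvalue), variant="shapiro-wilk")

    grouping = grouping.reindex(values.index)
    groups = [grp.to_numpy(float) for _, grp in values.groupby(grouping)]
    if any(len(g) == 0 for g in groups) or len(groups) < 2:
        raise AnalysisError("each group needs at least one observation, and >= 2 groups")
    summary = _group_summary(values, grouping)

    if test == "rank-sum":
        if len(groups) != 2:
            raise AnalysisError(f"rank-sum needs exactly 2 groups, got {len(groups)}")
        a, b = groups
        pooled = np.concatenate([a, b])
        has_ties = len(np.unique(pooled)) < len(pooled)
        if len(pooled) <= 20 and not has_ties:
            res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            variant = "exact"
        else:
            res = stats.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic", use_continuity=True
            )
            variant = "normal-approx, tie and continuity corrected"
        return TestResult("rank-sum", float(res.statistic), float(res.pvalue), variant, summary)

    if test == "kruskal":
        res = stats.kruskal(*groups)
        return TestResult("kruskal", float(res.statistic), float(res.pvalue), "chi2-approx", summary)

    raise AnalysisError(f"unknown test {test!r}")


def benjamini_hochberg(p_values: pd.Series) -> pd.Series:
    """BH-adjusted q-values (optional; no adjustment is applied by default)."""
    p = p_values.to_numpy(float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(q, 0, 1)
    return pd.Series(out, index=p_values.index, name="q_value")


def concordance(
    first: pd.DataFrame, second: pd.DataFrame, min_rho: float = 0.5
) -> pd.DataFrame:
    """Per-specimen Spearman concordance between two measurement sites.

    ``first`` and ``second`` are samples × antigens intensity tables sharing
    the same specimens (rows) and antigens (columns). Returns per-specimen
    rho with a pass flag (rho > ``min_rho``); the fraction passing is stored
    in ``DataFrame.attrs['fraction_passing']``.
    """
    if first.shape != second.shape or list(first.index) != list(second.index):
        raise AnalysisError("paired tables must share shape and specimen order")
    if first.shape[1] < 3:
        raise AnalysisError("need >= 3 antigens per pair for a rank correlation")
    rows = []
    for sid in first.index:
        rho = float(stats.spearmanr(first.loc[sid].to_numpy(float), second.loc[sid].to_numpy(float)).statistic)
        rows.append({"sample_id": sid, "rho": rho, "passed": bool(rho > min_rho)})
    out = pd.DataFrame(rows).set_index("sample_id")
    out.attrs["fraction_passing"] = float(out["passed"].mean())
    out.attrs["min_rho"] = float(min_rho)
    return out
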