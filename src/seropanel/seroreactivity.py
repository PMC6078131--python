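"""IQR cutoffs, seroreactivity calls, biomarker scores and serum scores.

The seroreactivity model: for each antigen a positivity cutoff is placed at

    cutoff = Q75 + 2.5 × IQR

over the normalized intensities of a stated basis sample set (all samples by
default; controls-only as an option). A sample is seroreactive ("positive")
for an antigen iff its intensity is strictly above the cutoff; for positive
calls the signal-to-cutoff ratio S/C = intensity / cutoff quantifies the
magnitude of the reaction. Quantiles use linear interpolation between order
statistics (the common "type 7" convention); the convention and basis are
recorded because the cutoffs depend on both.

Per antigen and cohort, the biomarker score is

    score = N_positive × (mean S/C)^(1/3)

reflecting both the frequency and the strength of the reactions. Antigens
are ranked by the patient − control score difference, and candidates are
those whose difference exceeds a threshold (default 5, strict).

The per-sample serum score over an antigen subset is the sum of the
normalized intensities (not the excess over the cutoff) at antigens where
the sample is positive; the breadth of response is the count of positive
antigens per sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import IntensityMatrix
from .errors import AnalysisError, DataError

CUTOFF_MULTIPLIER = 2.5
QUANTILE_METHOD = "linear"  # type-7: linear interpolation between order stats


@dataclass
class CutoffTable:
    """Per-antigen Q75, IQR and positivity cutoff, plus the basis used."""

    table: pd.DataFrame  # index antigen_id; columns q75, iqr, cutoff
    basis: str
    multiplier: float = CUTOFF_MULTIPLIER
    quantile_method: str = QUANTILE_METHOD

    def __post_init__(self) -> None:
        if (self.table["iqr"] < 0).any():
            raise DataError("negative IQR in cutoff table")
        if (self.table["cutoff"] < self.table["q75"] - 1e-12).any():
            raise DataError("cutoff below Q75 in cutoff table")

    @property
    def cutoffs(self) -> pd.Series:
        return self.table["cutoff"]


@dataclass
class SeroCalls:
    """Binary positivity and S/C ratios (NaN where not positive)."""

    positive: pd.DataFrame  # bool, samples × antigens
    sc_ratio: pd.DataFrame  # float, NaN where negative
    unscorable: list[str]  # antigens dropped for non-positive cutoffs

    def __post_init__(self) -> None:
        sc = self.sc_ratio.to_numpy(float)
        defined = ~np.isnan(sc)
        if (defined != self.positive.to_numpy(bool)).any():
            raise DataError("S/C ratio defined exactly where positive, violated")
        if (sc[defined] <= 1.0).any():
            raise DataError("S/C ratio must exceed 1 wherever defined")

    @property
    def antigen_ids(self) -> list[str]:
        return list(self.positive.columns)


def compute_cutoffs(
    matrix: IntensityMatrix,
    basis: str = "all",
    multiplier: float = CUTOFF_MULTIPLIER,
) -> CutoffTable:
    """Per-antigen cutoff = Q75 + multiplier × IQR over the basis samples.

    ``basis``: ``"all"`` (patients + controls) or ``"controls"``. At least 4
    basis samples are required for the quartiles to be meaningful.
    """
    if basis == "all":
        idx = matrix.values.index
    elif basis == "controls":
        idx = matrix.cohort_index("control")
    else:
        raise AnalysisError(f"cutoff basis must be 'all' or 'controls', got {basis!r}")
    if len(idx) == 0:
        raise AnalysisError(f"empty basis sample set ({basis!r})")
    if len(idx) < 4:
        raise AnalysisError(f"need >= 4 basis samples for quartiles, got {len(idx)}")

    X = matrix.values.loc[idx].to_numpy(float)
    q25, q75 = np.percentile(X, [25, 75], axis=0, method=QUANTILE_METHOD)
    iqr = q75 - q25
    table = pd.DataFrame(
        {"q75": q75, "iqr": iqr, "cutoff": q75 + multiplier * iqr},
        index=pd.Index(matrix.values.columns, name="antigen_id"),
    )
    return CutoffTable(table, basis=basis, multiplier=multiplier)


def dichotomize(matrix: IntensityMatrix, cutoffs: CutoffTable) -> SeroCalls:
    """Call positivity (intensity strictly above cutoff) and S/C ratios.

    Antigens with a non-positive cutoff (possible when an antigen is all
    zeros after background flooring) are unscorable: they are excluded from
    the calls with a warning.
    """
    missing = [a for a in matrix.values.columns if a not in cutoffs.table.index]
    if missing:
        raise AnalysisError(f"antigen(s) missing from cutoff table: {missing[:10]}")
    cut = cutoffs.cutoffs.reindex(matrix.values.columns)
    unscorable = list(cut.index[cut <= 0])
    if unscorable:
        warnings.warn(
            f"excluding {len(unscorable)} antigen(s) with non-positive cutoff: {unscorable[:5]}"
        )
    keep = [a for a in matrix.values.columns if a not in set(unscorable)]
    values = matrix.values[keep]
    cut = cut[keep]
    positive = values.gt(cut, axis=1)
    sc = values.div(cut, axis=1).where(positive)
    return SeroCalls(positive=positive, sc_ratio=sc, unscorable=unscorable)


def biomarker_scores(calls: SeroCalls, labels: pd.Series) -> pd.DataFrame:
    """Per-antigen, per-cohort biomarker scores and single-marker metrics.

    Returns a DataFrame indexed by antigen with columns:
    n_pos_patient, n_pos_control, mean_sc_patient, mean_sc_control,
    score_patient, score_control, score_diff, rank (dense, 1 = largest
    score_diff), sensitivity, specificity. A cohort with zero positive
    samples for an antigen contributes mean S/C = 0 and score 0.
    """
    bad = set(labels.unique()) - {"patient", "control"}
    if bad:
        raise AnalysisError(f"labels must be 'patient'/'control', got {sorted(bad)}")
    labels = labels.reindex(calls.positive.index)
    if labels.isna().any():
        raise AnalysisError("missing cohort label for some samples")

    out = {}
    for cohort in ("patient", "control"):
        idx = labels.index[labels == cohort]
        pos = calls.positive.loc[idx]
        sc = calls.sc_ratio.loc[idx]
        n_pos = pos.sum(axis=0).astype(int)
        mean_sc = sc.mean(axis=0).fillna(0.0)  # NaN-aware: mean over positives only
        out[f"n_pos_{cohort}"] = n_pos
        out[f"mean_sc_{cohort}"] = mean_sc
        out[f"score_{cohort}"] = n_pos * np.cbrt(mean_sc)
    table = pd.DataFrame(out)
    table.index.name = "antigen_id"
    table["score_diff"] = table["score_patient"] - table["score_control"]
    table["rank"] = table["score_diff"].rank(ascending=False, method="dense").astype(int)
    n_patients = int((labels == "patient").sum())
    n_controls = int((labels == "control").sum())
    if n_patients == 0 or n_controls == 0:
        raise AnalysisError("both cohorts must be non-empty")
    table["sensitivity"] = table["n_pos_patient"] / n_patients
    table["specificity"] = 1.0 - table["n_pos_control"] / n_controls
    return table


def select_candidates(table: pd.DataFrame, threshold: float = 5.0) -> list[str]:
    """Antigens whose score_diff strictly exceeds the threshold.

    Ordered by descending score_diff, ties broken by antigen id (stable).
    """
    selected = table.loc[table["score_diff"] > threshold]
    order = np.lexsort((selected.index.astype(str), -selected["score_diff"].to_numpy(float)))
    return list(selected.index[order])


@dataclass
class SerumScoreResult:
    """Per-sample serum scores and positive-antigen counts over a subset."""

    per_sample: pd.DataFrame  # index sample; columns serum_score, n_positive, cohort
    summary: pd.DataFrame  # per cohort: median, q25, q75 of serum_score and n_positive
    subset: list[str]


def serum_scores(
    matrix: IntensityMatrix, cutoffs: CutoffTable, subset: list[str] | None = None
) -> SerumScoreResult:
    """Sum of intensities above their cutoffs, per sample, over a subset.

    The serum score adds the full intensity (not the excess over the cutoff)
    of every subset antigen the sample is positive for; ``n_positive`` counts
    those antigens. Cohort medians and quartiles are summarized alongside.
    """
    if subset is None:
        subset = list(matrix.values.columns)
    if len(subset) == 0:
        raise AnalysisError("serum scores need a non-empty antigen subset")
    missing = [a for a in subset if a not in matrix.values.columns]
    if missing:
        raise AnalysisError(f"subset antigen(s) not in matrix: {missing[:10]}")
    values = matrix.values[subset]
    cut = cutoffs.cutoffs.reindex(subset)
    if cut.isna().any():
        raise AnalysisError("cutoffs missing for some subset antigens")
    positive = values.gt(cut, axis=1)
    score = values.where(positive, 0.0).sum(axis=1)
    n_pos = positive.sum(axis=1).astype(int)
    per_sample = pd.DataFrame(
        {"serum_score": score, "n_positive": n_pos, "cohort": matrix.labels}
    )
    rows = {}
    for cohort, grp in per_sample.groupby("cohort"):
        row = {}
        for col in ("serum_score", "n_positive"):
            v = grp[col].to_numpy(float)
            row[f"{col}_median"] = float(np.median(v))
            row[f"{col}_q25"] = float(np.percentile(v, 25))
            row[f"{col}_q75"] = float(np.percentile(v, 75))
        rows[cohort] = row
    summary = pd.DataFrame.from_dict(rows, orient="index")
    summary.index.name = "cohort"
    return SerumScoreResult(per_sample=per_sample, summary=summary, subset=list(subset))


def breadth_summary(
    calls: SeroCalls, labels: pd.Series, subset: list[str] | None = None
) -> pd.DataFrame:
    """Per-cohort breadth of response over an antigen subset.

    Returns, per cohort: median/Q25/Q75 of per-sample positive counts and the
    total number of positive responses.
    """
    if subset is None:
        subset = list(calls.positive.columns)
    missing = [a for a in subset if a not in calls.positive.columns]
    if missing:
        raise AnalysisError(f"subset antigen(s) not in calls: {missing[:10]}")
    labels = labels.reindex(calls.positive.index)
    counts = calls.positive[subset].sum(axis=1).astype(int)
    df = pd.DataFrame({"count": counts, "cohort": labels})
    rows = []
    for cohort, grp in df.groupby("cohort"):
        rows.append(
            {
                "cohort": cohort,
                "median": float(grp["count"].median()),
                "q25": float(np.percentile(grp["count"], 25)),
                "q75": float(np.percentile(grp["count"], 75)),
                "total_positive": int(grp["count"].sum()),
                "n_samples": int(len(grp)),
            }
        )
    return pd.DataFrame(rows).set_index("cohort")
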