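"""Spot-table I/O, replicate collapse, QC, and the two-step normalization.

The processing order is fixed and recorded in the matrix provenance:

    subtract background → collapse replicates (median of the replicate
    spots) → QC against the reference serum → intra-array normalization
    (divide each array by its overall median across antigens) → quantile
    normalization across arrays.

Intra-array normalization makes arrays comparable in scale (every array's
median becomes exactly 1); quantile normalization then forces all arrays
onto a common intensity distribution while preserving within-array ranks —
the classic ``normalize.quantiles`` behavior, including the tie rule
(tied values receive the mean of the rank-mean values over the tied range).

File formats (tab-delimited, text only; ``#``-prefixed header comments carry
a schema-version string):

* spot table ``<prefix>.spots.tsv``: array_id, antigen_id, replicate_idx,
  rfu, background_rfu; sibling ``<prefix>.arrays.tsv``: array_id, sample_id,
  cohort, batch.
* intensity matrix: samples as rows; first column sample_id, second column
  cohort, remaining columns one per antigen id.

Antigen ids starting with ``CTRL_`` denote control spots: they are excluded
from the intra-array normalization median and dropped from the analysis
matrix.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .containers import (
    ARRAY_COLUMNS,
    CONTROL_SPOT_PREFIX,
    SPOT_COLUMNS,
    IntensityMatrix,
    QCReport,
    SpotLevelDataset,
)
from .errors import DataError, FormatError, ParseError

SPOT_SCHEMA = "seropanel spot-table v1"
ARRAY_SCHEMA = "seropanel array-metadata v1"
MATRIX_SCHEMA = "seropanel intensity-matrix v1"


# ---------------------------------------------------------------------------
# I/O


def write_spot_table(dataset: SpotLevelDataset, prefix: str) -> tuple[str, str]:
    """Write ``<prefix>.spots.tsv`` and ``<prefix>.arrays.tsv``; return the paths."""
    spots_path, arrays_path = f"{prefix}.spots.tsv", f"{prefix}.arrays.tsv"
    with open(spots_path, "w") as fh:
        fh.write(f"# {SPOT_SCHEMA}\n")
        dataset.spots.to_csv(fh, sep="\t", index=False)
    with open(arrays_path, "w") as fh:
        fh.write(f"# {ARRAY_SCHEMA}\n")
        dataset.arrays.to_csv(fh, sep="\t", index=False)
    return spots_path, arrays_path


def read_spot_table(
    path: str, arrays_path: str | None = None, lenient: bool = False
) -> SpotLevelDataset:
    """Read a spot table (and its sibling array-metadata file).

    ``path`` is the ``.spots.tsv`` file; ``arrays_path`` defaults to the
    sibling ``.arrays.tsv``. In strict mode (default) a malformed row raises
    :class:`ParseError` with its line number; with ``lenient=True`` malformed
    rows are dropped with a warning instead.
    """
    if arrays_path is None:
        if not path.endswith(".spots.tsv"):
            raise FormatError(
                f"cannot infer array-metadata path from {path!r}; pass arrays_path"
            )
        arrays_path = path[: -len(".spots.tsv")] + ".arrays.tsv"

    spots = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in SPOT_COLUMNS if c not in spots.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {missing}")

    numeric = {}
    bad_rows = np.zeros(len(spots), dtype=bool)
    for col in ("rfu", "background_rfu", "replicate_idx"):
        converted = pd.to_numeric(spots[col], errors="coerce")
        bad = converted.isna().to_numpy() | ~np.isfinite(converted.to_numpy(float))
        bad_rows |= bad
        numeric[col] = converted
    if bad_rows.any():
        # +2: header comment line and column header precede data row 0
        lines = [int(i) + 3 for i in np.nonzero(bad_rows)[0]]
        if not lenient:
            raise ParseError(f"{path}: non-numeric value(s) at line(s) {lines[:10]}")
        warnings.warn(f"{path}: dropped {bad_rows.sum()} malformed row(s) at line(s) {lines[:10]}")
    for col, converted in numeric.items():
        spots[col] = converted
    spots = spots.loc[~bad_rows].reset_index(drop=True)
    spots["replicate_idx"] = spots["replicate_idx"].astype(int)

    arrays = pd.read_csv(arrays_path, sep="\t", comment="#", dtype=str)
    missing = [c for c in ARRAY_COLUMNS if c not in arrays.columns]
    if missing:
        raise FormatError(f"{arrays_path}: missing required column(s): {missing}")
    return SpotLevelDataset(spots, arrays)


def write_matrix(matrix: IntensityMatrix, path: str) -> str:
    with open(path, "w") as fh:
        fh.write(f"# {MATRIX_SCHEMA}; provenance: {','.join(matrix.provenance) or 'raw'}\n")
        out = matrix.values.copy()
        out.insert(0, "cohort", matrix.labels)
        out.index.name = "sample_id"
        out.to_csv(fh, sep="\t")
    return path


def read_matrix(path: str) -> IntensityMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if "cohort" not in df.columns:
        raise FormatError(f"{path}: missing required column 'cohort'")
    labels = df["cohort"]
    values = df.drop(columns=["cohort"]).astype(float)
    return IntensityMatrix(values, labels)


# ---------------------------------------------------------------------------
# Processing


def subtract_background(dataset: SpotLevelDataset) -> SpotLevelDataset:
    """Per-spot local background subtraction, floored at zero.

    Negative post-subtraction fluorescence is non-physical and would break
    the strictly-positive-median precondition of intra-array normalization,
    so ``rfu' = max(rfu − background_rfu, 0)``; the background column is
    zeroed afterwards.
    """
    out = dataset.copy()
    rfu = out.spots["rfu"].to_numpy(float) - out.spots["background_rfu"].to_numpy(float)
    out.spots["rfu"] = np.maximum(rfu, 0.0)
    out.spots["background_rfu"] = 0.0
    return out


def collapse_replicates(dataset: SpotLevelDataset) -> IntensityMatrix:
    """Median-collapse replicate spots into a samples × antigens matrix.

    Each (sample, antigen) cell is the median of its replicate spot rfu
    values (for four replicates: the mean of the two central values).
    Reference arrays are excluded from the analysis matrix but their
    collapsed profile is kept on ``matrix.reference`` for QC. Control-spot
    antigens (``CTRL_`` prefix) are dropped from the matrix. Per-array median
    replicate CV is recorded in ``matrix.sample_meta``.
    """
    spots = dataset.spots
    med = spots.groupby(["array_id", "antigen_id"], sort=True)["rfu"].agg(["median", "mean", "std", "count"])
    if (med["count"] < 1).any():
        raise DataError("array/antigen cell with zero replicates")

    wide = med["median"].unstack("antigen_id")
    meta_ids = set(dataset.arrays["array_id"])
    absent = sorted(meta_ids - set(wide.index))
    if absent:
        raise DataError(f"array(s) with no spot records: {absent[:10]}")
    if wide.isna().any().any():
        missing = wide.columns[wide.isna().any()].tolist()
        raise DataError(f"antigen(s) missing on some arrays: {missing[:10]}")

    # replicate CV per (array, antigen); median over antigens per array
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = (med["std"] / med["mean"]).replace([np.inf, -np.inf], np.nan)
    median_cv = cv.groupby("array_id").median()

    meta = dataset.arrays.set_index("array_id")
    is_ref = meta["cohort"] == "reference"
    ref_ids = meta.index[is_ref]
    reference = wide.loc[ref_ids].median(axis=0) if len(ref_ids) else None

    keep = meta.index[~is_ref]
    values = wide.loc[keep]
    values.index = meta.loc[keep, "sample_id"]
    values.index.name = "sample_id"
    labels = pd.Series(meta.loc[keep, "cohort"].to_numpy(), index=values.index, name="cohort")

    control_cols = [c for c in values.columns if str(c).startswith(CONTROL_SPOT_PREFIX)]
    values = values.drop(columns=control_cols)
    if reference is not None:
        reference = reference.drop(index=control_cols)

    sample_meta = pd.DataFrame(
        {
            "array_id": keep,
            "median_cv": median_cv.reindex(keep).to_numpy(),
        },
        index=values.index,
    )
    return IntensityMatrix(
        values, labels, reference=reference, sample_meta=sample_meta, provenance=["collapse"]
    )


def qc_arrays(
    matrix: IntensityMatrix, reference: pd.Series | None = None,
    min_rho: float = 0.5, max_cv: float = 0.5,
) -> QCReport:
    """Flag arrays discordant with the reference serum or with noisy replicates.

    An array fails if its Spearman correlation with the reference profile is
    below ``min_rho`` or its median replicate CV exceeds ``max_cv``.
    """
    if reference is None:
        reference = matrix.reference
    if reference is None:
        raise DataError("no reference profile available for QC")
    if matrix.n_antigens < 3:
        raise DataError("QC needs at least 3 antigens to compute a rank correlation")
    ref = reference.reindex(matrix.values.columns)
    if ref.isna().any():
        raise DataError("reference profile does not cover all antigens")

    rows = []
    for sample_id, row in matrix.values.iterrows():
        rho = float(spearmanr(row.to_numpy(float), ref.to_numpy(float)).statistic)
        cv = np.nan
        if matrix.sample_meta is not None and "median_cv" in matrix.sample_meta.columns:
            cv = float(matrix.sample_meta.loc[sample_id, "median_cv"])
        reasons = []
        if not np.isnan(rho) and rho < min_rho:
            reasons.append(f"rho {rho:.3f} < {min_rho}")
        if np.isnan(rho):
            reasons.append("rho undefined (constant array)")
        if not np.isnan(cv) and cv > max_cv:
            reasons.append(f"median replicate CV {cv:.3f} > {max_cv}")
        rows.append(
            {
                "array_id": sample_id,
                "rho": rho,
                "median_cv": cv,
                "passed": not reasons,
                "reason": "; ".join(reasons),
            }
        )
    return QCReport(pd.DataFrame(rows), min_rho=min_rho, max_cv=max_cv)


def drop_failed_arrays(matrix: IntensityMatrix, report: QCReport) -> IntensityMatrix:
    """Remove QC-failed arrays (exclusion, not imputation)."""
    keep = matrix.values.index[matrix.values.index.isin(report.passed_ids)]
    out = matrix.subset_samples(keep)
    out.provenance.append("qc")
    return out


def intra_array_normalize(matrix: IntensityMatrix) -> IntensityMatrix:
    """Divide each array by its overall median intensity across antigens.

    After the operation every array's median is exactly 1, removing
    array-to-array scale differences. Raises :class:`DataError` naming any
    array whose overall median is not strictly positive (degenerate array).
    """
    values = matrix.values.to_numpy(float)
    medians = np.median(values, axis=1)
    bad = matrix.values.index[medians <= 0].tolist()
    if bad:
        raise DataError(f"non-positive overall median for array(s): {bad[:10]}")
    out = matrix.copy()
    out.values = matrix.values.div(pd.Series(medians, index=matrix.values.index), axis=0)
    out.provenance.append("intra")
    return out


def quantile_normalize(matrix: IntensityMatrix) -> IntensityMatrix:
    """Force all arrays onto the common mean-quantile distribution.

    Classic quantile normalization: sort each array, average the order
    statistics across arrays, and give every array those averaged values in
    its own rank order. Tied values within an array receive the mean of the
    averaged order statistics over the tied rank range. After the operation
    every array's sorted value vector is identical; applying the operation
    twice equals applying it once.
    """
    X = matrix.values.to_numpy(float)
    n, p = X.shape
    mean_q = np.sort(X, axis=1).mean(axis=0)
    out = np.empty_like(X)
    for i in range(n):
        order = np.argsort(X[i], kind="mergesort")
        xs = X[i][order]
        starts = np.concatenate(([0], np.nonzero(np.diff(xs))[0] + 1))
        ends = np.concatenate((starts[1:], [p]))
        sums = np.add.reduceat(mean_q, starts)
        group_vals = sums / (ends - starts)
        expanded = np.repeat(group_vals, ends - starts)
        out[i, order] = expanded
    result = matrix.copy()
    result.values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    result.provenance.append("quantile")
    return result


def normalize_pipeline(
    dataset: SpotLevelDataset,
    min_rho: float = 0.5,
    max_cv: float = 0.5,
    skip_quantile: bool = False,
) -> tuple[IntensityMatrix, QCReport]:
    """Run subtract → collapse → QC-exclude → intra → (quantile)."""
    collapsed = collapse_replicates(subtract_background(dataset))
    report = qc_arrays(collapsed, min_rho=min_rho, max_cv=max_cv)
    matrix = intra_array_normalize(drop_failed_arrays(collapsed, report))
    if not skip_quantile:
        matrix = quantile_normalize(matrix)
    return matrix, report
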