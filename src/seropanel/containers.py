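"""Core in-memory containers shared across modules.

Two levels of data are distinguished. :class:`SpotLevelDataset` holds
pre-collapse replicate spot intensities, one record per spot, plus per-array
metadata (sample id, cohort, batch). :class:`IntensityMatrix` is the
pipeline's central object: a samples × antigens table of (normalized)
intensities with cohort labels, the collapsed reference-serum profile kept
aside for QC, and a provenance trail of the operations applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

SPOT_COLUMNS = ["array_id", "antigen_id", "replicate_idx", "rfu", "background_rfu"]
ARRAY_COLUMNS = ["array_id", "sample_id", "cohort", "batch"]
COHORTS = ("patient", "control", "reference")

#: Antigen ids starting with this prefix are control spots: excluded from the
#: intra-array normalization median and from the analysis matrix.
CONTROL_SPOT_PREFIX = "CTRL_"


@dataclass
class SpotLevelDataset:
    """Replicate-level spot intensities plus array metadata.

    ``spots`` columns: array_id, antigen_id, replicate_idx, rfu,
    background_rfu. ``arrays`` columns: array_id, sample_id, cohort, batch
    (one row per array; cohort in {patient, control, reference}).
    """

    spots: pd.DataFrame
    arrays: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SPOT_COLUMNS if c not in self.spots.columns]
        if missing:
            raise DataError(f"spot table missing column(s): {missing}")
        missing = [c for c in ARRAY_COLUMNS if c not in self.arrays.columns]
        if missing:
            raise DataError(f"array metadata missing column(s): {missing}")
        bad = set(self.arrays["cohort"]) - set(COHORTS)
        if bad:
            raise DataError(f"unknown cohort label(s): {sorted(bad)}; expected one of {COHORTS}")
        if not np.isfinite(self.spots["rfu"].to_numpy(float)).all():
            raise DataError("non-finite rfu values in spot table")

    @property
    def array_ids(self) -> list[str]:
        return list(self.arrays["array_id"])

    @property
    def antigen_ids(self) -> list[str]:
        return sorted(self.spots["antigen_id"].unique())

    def copy(self) -> "SpotLevelDataset":
        return SpotLevelDataset(self.spots.copy(), self.arrays.copy())


@dataclass
class IntensityMatrix:
    """Samples × antigens intensity matrix with cohort labels.

    ``values``: DataFrame indexed by sample id, columns are antigen ids.
    ``labels``: cohort per sample ('patient' or 'control'), aligned to
    ``values.index``. ``reference``: the collapsed reference-serum intensity
    profile (Series over antigens) or None. ``sample_meta`` carries per-array
    QC covariates (median replicate CV). ``provenance`` records the
    operations applied, in order.
    """

    values: pd.DataFrame
    labels: pd.Series
    reference: pd.Series | None = None
    sample_meta: pd.DataFrame | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.labels.index):
            self.labels = self.labels.reindex(self.values.index)
        if self.labels.isna().any():
            raise DataError("cohort label missing for some samples")
        bad = set(self.labels.unique()) - {"patient", "control"}
        if bad:
            raise DataError(f"analysis matrix labels must be patient/control, got {sorted(bad)}")
        if self.values.isna().any().any():
            raise DataError("intensity matrix contains missing values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_antigens(self) -> int:
        return self.values.shape[1]

    @property
    def antigen_ids(self) -> list[str]:
        return list(self.values.columns)

    def cohort_index(self, cohort: str) -> pd.Index:
        return self.values.index[self.labels == cohort]

    def copy(self) -> "IntensityMatrix":
        return IntensityMatrix(
            self.values.copy(),
            self.labels.copy(),
            None if self.reference is None else self.reference.copy(),
            None if self.sample_meta is None else self.sample_meta.copy(),
            list(self.provenance),
        )

    def subset_samples(self, index: pd.Index) -> "IntensityMatrix":
        return IntensityMatrix(
            self.values.loc[index],
            self.labels.loc[index],
            self.reference,
            None if self.sample_meta is None else self.sample_meta.loc[self.sample_meta.index.intersection(index)],
            list(self.provenance),
        )


@dataclass
class QCReport:
    """Per-array quality-control outcome.

    ``table`` columns: array_id, rho (Spearman vs reference), median_cv,
    passed (bool), reason (empty when passed).
    """

    table: pd.DataFrame
    min_rho: float
    max_cv: float

    def __post_init__(self) -> None:
        required = ["array_id", "rho", "median_cv", "passed", "reason"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise DataError(f"QC report missing column(s): {missing}")
        failed = self.table[~self.table["passed"]]
        if (failed["reason"].astype(str) == "").any():
            raise DataError("failed arrays must carry a non-empty reason")

    @property
    def passed_ids(self) -> list[str]:
        return list(self.table.loc[self.table["passed"], "array_id"])

    @property
    def failed_ids(self) -> list[str]:
        return list(self.table.loc[~self.table["passed"], "array_id"])
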