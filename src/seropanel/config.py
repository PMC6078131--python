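"""Configuration objects and the seed-spawning scheme.

A single master seed drives every stochastic stage. Stage seeds are derived
with :func:`numpy.random.SeedSequence` using the master seed as entropy and a
fixed per-stage key, so each stage is independently reproducible:

    stage_seed = SeedSequence((master_seed, STAGE_KEYS[stage])).generate_state(1)[0] % 2**31

Within the forest stage, run ``i`` uses ``SeedSequence((master_seed,
STAGE_KEYS['forest'], i))`` — a documented counter scheme, so re-running any
single forest out of the 1000 reproduces it exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from typing import Any, Mapping

import numpy as np
import yaml

from .errors import ConfigError

#: Fixed keys for per-stage seed derivation.
STAGE_KEYS: dict[str, int] = {
    "simulate": 1,
    "qc": 2,
    "forest": 3,
    "tree": 4,
    "evaluate": 5,
}


def stage_seed(master_seed: int, stage: str, counter: int | None = None) -> int:
    """Derive a 31-bit stage seed from the master seed.

    ``counter`` addresses repeated sub-units within a stage (e.g. forest runs).
    """
    if stage not in STAGE_KEYS:
        raise ConfigError(f"unknown stage {stage!r}; known: {sorted(STAGE_KEYS)}")
    entropy: tuple[int, ...] = (int(master_seed), STAGE_KEYS[stage])
    if counter is not None:
        entropy = entropy + (int(counter),)
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % 2**31)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic serology cohort generator.

    The generator emulates a high-density antigen microarray screen:
    ``n_antigens`` proteins spotted in ``n_replicates`` replicate spots per
    array, one array per serum sample, patient and control cohorts, and a
    small set of "planted" antigens against which patients raise
    autoantibodies more often than controls.

    Intensities are lognormal: each antigen has a baseline drawn once
    (log-mean ``background_log_mean``, log-sd ``background_log_sd``), each
    (sample, antigen) latent intensity adds sample noise (``sample_log_sd``)
    and a per-array batch scale factor (``batch_log_sd``), and each replicate
    spot adds spot noise (``replicate_log_sd``). A positive reaction
    multiplies the latent intensity by ``spike_magnitude`` (jittered with
    ``spike_log_sd``).
    """

    n_antigens: int = 1627
    n_patients: int = 104
    n_controls: int = 105
    n_planted: int = 139
    spike_prob_patient: float = 0.15
    spike_prob_control: float = 0.02
    spike_magnitude: float = 6.0
    spike_log_sd: float = 0.3
    background_log_mean: float = float(np.log(500.0))
    background_log_sd: float = 0.8
    sample_log_sd: float = 0.35
    batch_log_sd: float = 0.1
    replicate_log_sd: float = 0.15
    background_spot_log_mean: float = float(np.log(50.0))
    background_spot_log_sd: float = 0.3
    n_replicates: int = 4
    qc_fail_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_antigens", "n_patients", "n_controls", "n_replicates"):
            if int(getattr(self, name)) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0 <= self.n_planted <= self.n_antigens:
            raise ConfigError(
                f"n_planted must be in [0, n_antigens], got {self.n_planted}"
            )
        for name in ("spike_prob_patient", "spike_prob_control", "qc_fail_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_planted > 0 and self.spike_prob_patient <= self.spike_prob_control:
            raise ConfigError(
                "spike_prob_patient must exceed spike_prob_control for planted antigens"
            )
        for name in (
            "spike_magnitude",
            "spike_log_sd",
            "background_log_sd",
            "sample_log_sd",
            "batch_log_sd",
            "replicate_log_sd",
            "background_spot_log_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0, got {getattr(self, name)}")

    @classmethod
    def recovery_default(cls, seed: int = 0, **overrides: Any) -> "SimConfig":
        """The scaled-down cohort used throughout the recovery checks.

        200 antigens of which 15 are planted, 100 patients + 100 controls,
        spike probabilities 0.15 / 0.02.
        """
        kwargs: dict[str, Any] = dict(
            n_antigens=200,
            n_planted=15,
            n_patients=100,
            n_controls=100,
            spike_prob_patient=0.15,
            spike_prob_control=0.02,
            seed=seed,
        )
        kwargs.update(overrides)
        return cls(**kwargs)


def _coerce_section(cls: type, data: Mapping[str, Any], section: str) -> Any:
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in [{section}]: {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end pipeline configuration.

    Defaults mirror the study's stated constants: cutoff multiplier 2.5 over
    the 75th percentile, candidate threshold > 5 on the patient−control
    biomarker-score difference, top-20 rank scores, 1000 forest runs and a
    panel of at most 10 markers.
    """

    input_spots: str | None = None
    input_matrix: str | None = None
    outdir: str = "seropanel_out"
    simulate: SimConfig | None = None
    # normalization / QC
    skip_quantile: bool = False
    min_rho: float = 0.5
    max_cv: float = 0.5
    # seroreactivity
    cutoff_basis: str = "all"  # or "controls"
    cutoff_multiplier: float = 2.5
    candidate_threshold: float = 5.0
    frozen_cutoffs: bool = False
    # panel selection
    n_runs: int = 1000
    n_trees: int = 500
    top_k: int = 20
    max_panel_size: int = 10
    cv_folds: int = 10
    prune_rule: str = "cap"  # or "1se" / "min" (CV-pruned tree-rule classifier)
    forest_mode: str = "regression"  # or "classification"
    importance_repeats: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cutoff_basis not in ("all", "controls"):
            raise ConfigError(f"cutoff_basis must be 'all' or 'controls', got {self.cutoff_basis!r}")
        if self.prune_rule not in ("cap", "1se", "min"):
            raise ConfigError(f"prune_rule must be 'cap', '1se' or 'min', got {self.prune_rule!r}")
        if self.forest_mode not in ("regression", "classification"):
            raise ConfigError(
                f"forest_mode must be 'regression' or 'classification', got {self.forest_mode!r}"
            )
        for name in ("cutoff_multiplier", "n_runs", "n_trees", "top_k", "max_panel_size", "cv_folds"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        n_inputs = sum(x is not None for x in (self.input_spots, self.input_matrix, self.simulate))
        if n_inputs > 1:
            raise ConfigError("give at most one of input_spots, input_matrix, simulate")

    @classmethod
    def from_yaml(cls, path: str, **overrides: Any) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        raw.update(overrides)
        sim = raw.pop("simulate", None)
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        if sim is not None:
            sim_cfg = _coerce_section(SimConfig, sim, "simulate")
            object.__setattr__(cfg, "simulate", sim_cfg)
        return cfg

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        return d
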