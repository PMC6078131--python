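"""Synthetic serology-cohort generator with planted seroreactive antigens.

The generator emulates a high-density protein-microarray autoantibody screen:
one array per serum sample, every antigen spotted in replicate, lognormal
right-skewed background intensities with an antigen-specific baseline shared
across samples, a multiplicative per-array batch scale factor, and a small
set of "planted" antigens for which patients are seroreactive more often than
controls. Positivity is a latent Bernoulli per (sample, planted antigen)
expressed as a multiplicative intensity spike, mirroring the positive/negative
semantics the downstream scoring uses. Ground truth (which antigens were
planted, and which samples reacted) is returned alongside, so recovery of the
planted signal can be measured exactly.

All randomness derives from ``SimConfig.seed`` through fixed sub-streams:
antigen baselines, cohort draws, the reference serum and QC corruption each
have their own :class:`numpy.random.SeedSequence` key. The reference serum
and the antigen baselines therefore reproduce independently of cohort size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SimConfig
from .containers import SpotLevelDataset
from .errors import ConfigError, DataError

# SeedSequence sub-keys: antigen baselines / planted choice / cohort draws /
# reference / QC.
_KEY_BASE, _KEY_PLANTED, _KEY_COHORT, _KEY_REFERENCE, _KEY_QC = 11, 15, 12, 13, 14

REFERENCE_SAMPLE_ID = "REFERENCE"


@dataclass
class GroundTruth:
    """Simulation truth: planted antigens and per-sample reactivity.

    ``spike_probs``: DataFrame indexed by planted antigen id with columns
    patient/control giving the true per-cohort reaction probability.
    ``indicators``: boolean DataFrame (samples × planted antigens), True where
    the latent Bernoulli fired (an actual planted reaction).
    """

    planted_antigen_ids: list[str]
    spike_probs: pd.DataFrame
    indicators: pd.DataFrame

    def __post_init__(self) -> None:
        if set(self.spike_probs.index) != set(self.planted_antigen_ids):
            raise DataError("spike_probs index must equal the planted antigen set")
        if list(self.indicators.columns) != self.planted_antigen_ids:
            raise DataError("indicator columns must match planted_antigen_ids")

    def to_json(self, path: str) -> None:
        payload = {
            "planted_antigen_ids": self.planted_antigen_ids,
            "spike_probs": self.spike_probs.to_dict(orient="index"),
            "indicators": {
                s: [bool(v) for v in row]
                for s, row in zip(self.indicators.index, self.indicators.to_numpy())
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        planted = payload["planted_antigen_ids"]
        probs = pd.DataFrame.from_dict(payload["spike_probs"], orient="index").loc[planted]
        ind = pd.DataFrame.from_dict(payload["indicators"], orient="index")
        ind.columns = planted
        return cls(planted, probs, ind.astype(bool))


def _antigen_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"AG_{i:0{width}d}" for i in range(1, n + 1)]


def _rng(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), key)))


def _antigen_baselines(config: SimConfig) -> np.ndarray:
    """Per-antigen lognormal baseline (log scale), drawn once per seed."""
    rng = _rng(config.seed, _KEY_BASE)
    return rng.normal(config.background_log_mean, config.background_log_sd, config.n_antigens)


def _spots_from_latent(
    latent_log: np.ndarray,
    array_ids: list[str],
    antigens: list[str],
    config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Expand latent (array × antigen) log-intensities into replicate spot records."""
    n_arrays, n_antigens = latent_log.shape
    r = config.n_replicates
    spot_noise = rng.normal(0.0, config.replicate_log_sd, (n_arrays, n_antigens, r))
    signal = np.exp(latent_log[:, :, None] + spot_noise)
    background = np.exp(
        rng.normal(config.background_spot_log_mean, config.background_spot_log_sd, signal.shape)
    )
    return pd.DataFrame(
        {
            "array_id": np.repeat(array_ids, n_antigens * r),
            "antigen_id": np.tile(np.repeat(antigens, r), n_arrays),
            "replicate_idx": np.tile(np.arange(1, r + 1), n_arrays * n_antigens),
            "rfu": (signal + background).ravel(),
            "background_rfu": background.ravel(),
        }
    )


def generate_cohort(
    config: SimConfig, cohort_seed: int | None = None
) -> tuple[SpotLevelDataset, GroundTruth]:
    """Generate a full synthetic cohort plus its ground truth.

    One array per sample (patients then controls) and one reference-serum
    array. Planted antigens are chosen at random among all antigens; in a
    "positive" sample their latent intensity is multiplied by
    ``spike_magnitude`` (lognormal jitter ``spike_log_sd``). Deterministic
    given ``config.seed``. If ``config.qc_fail_rate > 0`` the corresponding
    fraction of sample arrays is corrupted via :func:`inject_qc_failures`.

    ``cohort_seed`` redraws only the sample-level randomness (sample noise,
    spikes, replicate spots) while keeping the antigen baselines and the
    planted antigen set of ``config.seed`` — an independent validation cohort
    screened on the same array.
    """
    antigens = _antigen_ids(config.n_antigens)
    base = _antigen_baselines(config)
    planted_idx = np.sort(
        _rng(config.seed, _KEY_PLANTED).choice(
            config.n_antigens, size=config.n_planted, replace=False
        )
    )
    planted = [antigens[i] for i in planted_idx]
    rng = _rng(config.seed if cohort_seed is None else cohort_seed, _KEY_COHORT)

    n = config.n_patients + config.n_controls
    sample_ids = [f"P_{i:03d}" for i in range(1, config.n_patients + 1)] + [
        f"C_{i:03d}" for i in range(1, config.n_controls + 1)
    ]
    cohorts = ["patient"] * config.n_patients + ["control"] * config.n_controls
    array_ids = [f"ARR_{i:03d}" for i in range(1, n + 1)]

    batch_log = rng.normal(0.0, config.batch_log_sd, n)
    latent = (
        base[None, :]
        + rng.normal(0.0, config.sample_log_sd, (n, config.n_antigens))
        + batch_log[:, None]
    )

    p = np.where(np.array(cohorts) == "patient", config.spike_prob_patient, config.spike_prob_control)
    indicators = rng.random((n, config.n_planted)) < p[:, None]
    spike = np.log(config.spike_magnitude) + rng.normal(0.0, config.spike_log_sd, indicators.shape)
    latent[:, planted_idx] += np.where(indicators, spike, 0.0)

    spots = _spots_from_latent(latent, array_ids, antigens, config, rng)

    ref = generate_reference_serum(config)
    spots = pd.concat([spots, ref.spots], ignore_index=True)

    arrays = pd.DataFrame(
        {
            "array_id": array_ids + list(ref.arrays["array_id"]),
            "sample_id": sample_ids + list(ref.arrays["sample_id"]),
            "cohort": cohorts + list(ref.arrays["cohort"]),
            "batch": "B1",
        }
    )
    dataset = SpotLevelDataset(spots, arrays)

    truth = GroundTruth(
        planted_antigen_ids=planted,
        spike_probs=pd.DataFrame(
            {"patient": config.spike_prob_patient, "control": config.spike_prob_control},
            index=pd.Index(planted, name="antigen_id"),
        ),
        indicators=pd.DataFrame(indicators, index=pd.Index(sample_ids, name="sample_id"), columns=planted),
    )

    if config.qc_fail_rate > 0:
        eff = config.seed if cohort_seed is None else cohort_seed
        dataset = inject_qc_failures(
            dataset,
            config.qc_fail_rate,
            seed=int(np.random.SeedSequence((eff, _KEY_QC)).generate_state(1)[0] % 2**31),
        )
    return dataset, truth


def generate_reference_serum(config: SimConfig) -> SpotLevelDataset:
    """One reference-serum array drawn from the background model (no spikes).

    Shares the per-antigen baselines of the cohort generated from the same
    seed, so a clean sample array correlates strongly with it while a
    corrupted one does not. Stored under the reserved sample id
    ``REFERENCE``.
    """
    antigens = _antigen_ids(config.n_antigens)
    base = _antigen_baselines(config)
    rng = _rng(config.seed, _KEY_REFERENCE)
    latent = (base + rng.normal(0.0, config.sample_log_sd, config.n_antigens))[None, :]
    spots = _spots_from_latent(latent, ["ARR_REF"], antigens, config, rng)
    arrays = pd.DataFrame(
        {
            "array_id": ["ARR_REF"],
            "sample_id": [REFERENCE_SAMPLE_ID],
            "cohort": ["reference"],
            "batch": ["B1"],
        }
    )
    return SpotLevelDataset(spots, arrays)


def inject_qc_failures(dataset: SpotLevelDataset, rate: float, seed: int) -> SpotLevelDataset:
    """Corrupt a Binomial(n_arrays, rate) subset of sample arrays.

    Corrupted arrays get their spot intensities replaced by i.i.d. lognormal
    noise matched to the array's own scale, destroying the antigen structure
    (and hence the rank correlation with the reference). Reference arrays are
    never corrupted. Flags are recorded in a ``qc_corrupted`` column of the
    array metadata.
    """
    if not 0.0 <= rate <= 1.0:
        raise ConfigError(f"qc_fail_rate must be in [0, 1], got {rate}")
    out = dataset.copy()
    if "qc_corrupted" not in out.arrays.columns:
        out.arrays["qc_corrupted"] = False
    if rate == 0.0:
        return out
    rng = np.random.default_rng(seed)
    eligible = out.arrays.loc[out.arrays["cohort"] != "reference", "array_id"].to_numpy()
    flags = rng.random(len(eligible)) < rate
    corrupted = set(eligible[flags])
    if corrupted:
        mask = out.spots["array_id"].isin(corrupted).to_numpy()
        log_rfu = np.log(np.maximum(out.spots.loc[mask, "rfu"].to_numpy(float), 1e-9))
        noise = rng.normal(log_rfu.mean(), max(log_rfu.std(), 1e-6), mask.sum())
        rfu = out.spots["rfu"].to_numpy(float).copy()
        rfu[mask] = np.exp(noise)
        out.spots["rfu"] = rfu
        out.arrays.loc[out.arrays["array_id"].isin(corrupted), "qc_corrupted"] = True
    return out
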