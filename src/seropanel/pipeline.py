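"""End-to-end orchestration: simulate/ingest → QC → normalize → discover →
panel → evaluate, with a run manifest for reproducibility.

Every stochastic stage derives its seed from the single master seed in the
configuration (see :mod:`seropanel.config`), so a re-run with the same
configuration reproduces every stage output bit-identically. The manifest
records the configuration snapshot, package version, per-stage output file
hashes and counts (arrays dropped by QC, antigens dropped as unscorable,
candidates, panel members), and timestamps; hashes chain stage to stage so a
tampered intermediate is detectable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import pandas as pd
from sklearn.tree import export_text

from . import __version__
from .array_io import (
    collapse_replicates,
    drop_failed_arrays,
    intra_array_normalize,
    qc_arrays,
    quantile_normalize,
    read_matrix,
    read_spot_table,
    subtract_background,
    write_matrix,
)
from .config import PipelineConfig, SimConfig, stage_seed
from .containers import IntensityMatrix
from .errors import AnalysisError, DataError, SeropanelError
from .evaluation import compare_groups, roc_auc
from .panel import (
    aggregate_runs,
    any_positive_classify,
    fit_panel_tree,
    run_forests,
    select_stage2_features,
)
from .seroreactivity import (
    biomarker_scores,
    breadth_summary,
    compute_cutoffs,
    dichotomize,
    select_candidates,
    serum_scores,
)
from .simulate import generate_cohort


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class RunManifest:
    """Stage-by-stage record of one pipeline run."""

    def __init__(self, config: PipelineConfig, outdir: Path):
        self.outdir = outdir
        self.data: dict = {
            "package": "seropanel",
            "version": __version__,
            "config": config.to_dict(),
            "stages": [],
        }

    def add_stage(self, name: str, outputs: list[Path], counts: dict) -> None:
        prev = self.data["stages"][-1]["chain_hash"] if self.data["stages"] else ""
        hashes = {p.name: _sha256(p) for p in outputs}
        chain = hashlib.sha256(
            (prev + json.dumps(hashes, sort_keys=True)).encode()
        ).hexdigest()
        self.data["stages"].append(
            {
                "stage": name,
                "outputs": hashes,
                "counts": counts,
                "chain_hash": chain,
                "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            }
        )

    def write(self) -> Path:
        path = self.outdir / "manifest.json"
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=1, sort_keys=True)
        return path

    def without_timestamps(self) -> dict:
        d = json.loads(json.dumps(self.data))
        for st in d["stages"]:
            st.pop("timestamp", None)
        return d


def _write_tsv(df: pd.DataFrame, path: Path, schema: str) -> Path:
    with open(path, "w") as fh:
        fh.write(f"# seropanel {schema} v1\n")
        df.to_csv(fh, sep="\t")
    return path


def run_all(config: PipelineConfig) -> RunManifest:
    """Execute the full pipeline under one configuration; return the manifest.

    Stage order: acquire (simulate or ingest) → background subtraction →
    replicate collapse → QC exclusion → intra-array normalization →
    quantile normalization → cutoffs/calls/biomarker scores → candidate
    selection → serum scores and breadth → forest rank aggregation → tree
    panel → evaluation. Outputs are TSV/JSON files in ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config, outdir)

    # --- acquire ----------------------------------------------------------
    truth = None
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=stage_seed(config.seed, "simulate"))
        dataset, truth = generate_cohort(sim)
        truth_path = outdir / "truth.json"
        truth.to_json(str(truth_path))
        manifest.add_stage(
            "simulate",
            [truth_path],
            {
                "n_arrays": len(dataset.arrays),
                "n_antigens": sim.n_antigens,
                "n_planted": sim.n_planted,
                "sim_seed": sim.seed,
            },
        )
    elif config.input_spots is not None:
        dataset = read_spot_table(config.input_spots)
        manifest.add_stage("ingest", [], {"n_arrays": len(dataset.arrays)})
    elif config.input_matrix is not None:
        dataset = None
    else:
        raise DataError("no input: set one of simulate, input_spots, input_matrix")

    # --- normalize --------------------------------------------------------
    if dataset is not None:
        collapsed = collapse_replicates(subtract_background(dataset))
        report = qc_arrays(collapsed, min_rho=config.min_rho, max_cv=config.max_cv)
        qc_path = _write_tsv(report.table.set_index("array_id"), outdir / "qc_report.tsv", "qc-report")
        matrix = intra_array_normalize(drop_failed_arrays(collapsed, report))
        n_dropped = len(report.failed_ids)
    else:
        matrix = read_matrix(config.input_matrix)
        matrix = intra_array_normalize(matrix)
        qc_path = None
        n_dropped = 0
    if not config.skip_quantile:
        matrix = quantile_normalize(matrix)
    matrix_path = write_matrix(matrix, str(outdir / "normalized_matrix.tsv"))
    manifest.add_stage(
        "normalize",
        [p for p in (qc_path, Path(matrix_path)) if p is not None],
        {
            "n_samples": matrix.n_samples,
            "n_antigens": matrix.n_antigens,
            "arrays_dropped_by_qc": n_dropped,
            "provenance": ",".join(matrix.provenance),
        },
    )

    # --- discover ---------------------------------------------------------
    cutoffs = compute_cutoffs(matrix, basis=config.cutoff_basis, multiplier=config.cutoff_multiplier)
    calls = dichotomize(matrix, cutoffs)
    scores = biomarker_scores(calls, matrix.labels)
    candidates = select_candidates(scores, threshold=config.candidate_threshold)
    if not candidates:
        raise AnalysisError("no candidate antigens exceeded the score-difference threshold")

    cutoff_path = _write_tsv(cutoffs.table, outdir / "cutoffs.tsv", "cutoff-table")
    scores_path = _write_tsv(scores, outdir / "biomarker_scores.tsv", "biomarker-scores")
    cand_path = outdir / "candidates.txt"
    cand_path.write_text("".join(f"{a}\n" for a in candidates))
    serum = serum_scores(matrix, cutoffs, subset=candidates)
    serum_path = _write_tsv(serum.per_sample, outdir / "serum_scores.tsv", "serum-scores")
    breadth = breadth_summary(calls, matrix.labels, subset=candidates)
    breadth_path = _write_tsv(breadth, outdir / "breadth.tsv", "breadth-summary")
    manifest.add_stage(
        "discover",
        [cutoff_path, scores_path, cand_path, serum_path, breadth_path],
        {
            "cutoff_basis": cutoffs.basis,
            "n_candidates": len(candidates),
            "n_unscorable": len(calls.unscorable),
        },
    )

    # --- panel ------------------------------------------------------------
    features = matrix.values[candidates]
    if features.shape[1] < 2:
        raise AnalysisError("need at least 2 candidate antigens for the forest stage")
    runs = run_forests(
        features,
        matrix.labels,
        n_runs=config.n_runs,
        master_seed=config.seed,
        n_trees=config.n_trees,
        mode=config.forest_mode,
        importance_repeats=config.importance_repeats,
    )
    aggregation = aggregate_runs(runs)
    stage2 = select_stage2_features(aggregation, rule="union")
    model = fit_panel_tree(
        matrix.values[stage2],
        matrix.labels,
        max_panel_size=config.max_panel_size,
        cv_folds=config.cv_folds,
        seed=stage_seed(config.seed, "tree"),
        calls=calls,
        prune_rule=config.prune_rule,
    )
    agg_path = _write_tsv(aggregation.table, outdir / "rank_aggregation.tsv", "rank-aggregation")
    panel_path = outdir / "panel.txt"
    panel_path.write_text("".join(f"{a}\n" for a in model.panel))
    tree_path = outdir / "tree.txt"
    tree_path.write_text(export_text(model.tree, feature_names=model.feature_names))
    cum_path = _write_tsv(model.cumulative, outdir / "cumulative_metrics.tsv", "cumulative-metrics")
    manifest.add_stage(
        "panel",
        [agg_path, panel_path, tree_path, cum_path],
        {
            "n_runs": config.n_runs,
            "union_size": len(stage2),
            "panel_size": len(model.panel),
            "ccp_alpha": model.ccp_alpha,
        },
    )

    # --- evaluate ---------------------------------------------------------
    tree_roc = roc_auc(model.per_sample_prob, matrix.labels)
    anypos = any_positive_classify(calls, model.panel)
    anypos_roc = roc_auc(anypos["n_panel_positive"].astype(float), matrix.labels)
    serum_test = compare_groups(serum.per_sample["serum_score"], matrix.labels, test="rank-sum")
    metrics = pd.DataFrame(
        [
            {
                "rule": "tree",
                "sensitivity": model.tree_sensitivity,
                "specificity": model.tree_specificity,
                "auc": tree_roc.auc,
            },
            {
                "rule": "any_positive",
                "sensitivity": model.anypos_sensitivity,
                "specificity": model.anypos_specificity,
                "auc": anypos_roc.auc,
            },
        ]
    ).set_index("rule")
    metrics_path = _write_tsv(metrics, outdir / "panel_metrics.tsv", "panel-metrics")
    roc_path = _write_tsv(tree_roc.points, outdir / "roc_points.tsv", "roc-points")
    manifest.add_stage(
        "evaluate",
        [metrics_path, roc_path],
        {
            "tree_auc": tree_roc.auc,
            "anypos_auc": anypos_roc.auc,
            "serum_score_rank_sum_p": serum_test.p_value,
            "serum_score_test_variant": serum_test.variant,
        },
    )

    manifest.write()
    return manifest


def report(outdir: str) -> str:
    """One-page markdown summary of a completed run."""
    out = Path(outdir)
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        raise DataError(f"no manifest.json in {outdir}; run the pipeline first")
    with open(manifest_path) as fh:
        data = json.load(fh)
    stages = {s["stage"]: s for s in data["stages"]}
    for required in ("normalize", "discover", "panel", "evaluate"):
        if required not in stages:
            raise DataError(f"stage {required!r} missing from manifest")
    panel_file = out / "panel.txt"
    panel = panel_file.read_text().split() if panel_file.exists() else []
    metrics = pd.read_csv(out / "panel_metrics.tsv", sep="\t", comment="#", index_col=0)

    lines = [
        "# seropanel run report",
        "",
        f"Package version: {data['version']}",
        f"Master seed: {data['config']['seed']}",
        "",
        "## Cohort",
        f"- samples retained after QC: {stages['normalize']['counts']['n_samples']}",
        f"- antigens: {stages['normalize']['counts']['n_antigens']}",
        f"- arrays dropped by QC: {stages['normalize']['counts']['arrays_dropped_by_qc']}",
        f"- normalization: {stages['normalize']['counts']['provenance']}",
        "",
        "## Discovery",
        f"- cutoff basis: {stages['discover']['counts']['cutoff_basis']}"
        f" (cutoff = Q75 + {data['config']['cutoff_multiplier']} x IQR)",
        f"- candidates (score difference > {data['config']['candidate_threshold']}): "
        f"{stages['discover']['counts']['n_candidates']}",
        f"- unscorable antigens: {stages['discover']['counts']['n_unscorable']}",
        "",
        "## Panel",
        f"- forest runs: {stages['panel']['counts']['n_runs']}; top-20 union size: "
        f"{stages['panel']['counts']['union_size']}",
        f"- panel ({stages['panel']['counts']['panel_size']} markers, first-use order): "
        + ", ".join(panel),
        "",
        "## Performance (training cohort)",
    ]
    for rule, row in metrics.iterrows():
        lines.append(
            f"- {rule}: sensitivity {row['sensitivity']:.3f}, specificity "
            f"{row['specificity']:.3f}, AUC {row['auc']:.3f}"
        )
    lines += [
        "",
        f"Serum-score rank-sum p (patients vs controls): "
        f"{stages['evaluate']['counts']['serum_score_rank_sum_p']:.3g} "
        f"({stages['evaluate']['counts']['serum_score_test_variant']})",
    ]
    return "\n".join(lines) + "\n"
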