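"""Two-stage diagnostic panel selection.

Stage 1 fits many random forests (by default 1000, each with its own derived
seed) of the cohort label on the candidate antigens' normalized intensities
and records each forest's 20 most important antigens, scored 20 (most
important) down to 1. Over all runs, each antigen that ever entered a top-20
list gets an inclusion proportion (fraction of runs) and an average rank
score; their product is the weighted mean rank (WMR), the overall importance
used to reduce the candidate list to the union of top-20 members.

Stage 2 grows a binary classification tree (CART, Gini impurity) on the
reduced list, prunes it by cost-complexity with a cross-validated 1-SE rule,
and — if the tree still uses more distinct antigens than the panel cap —
prunes further (larger complexity penalties) until at most ``max_panel_size``
distinct split antigens remain. The panel is the distinct split antigens in
first-use (pre-order) order.

Two decision rules are evaluated: the tree's own leaf-probability rule, and
the "any-positive" rule (a sample is called a patient iff it is seroreactive
for at least one panel antigen), whose integer positive-marker count also
serves as a ROC score.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .config import stage_seed
from .errors import AnalysisError
from .seroreactivity import SeroCalls

TOP_K = 20


def _binary_labels(labels: pd.Series) -> np.ndarray:
    bad = set(pd.unique(labels)) - {"patient", "control"}
    if bad:
        raise AnalysisError(f"labels must be 'patient'/'control', got {sorted(bad)}")
    y = (labels.to_numpy() == "patient").astype(float)
    if len(np.unique(y)) < 2:
        raise AnalysisError("both classes must be present")
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise AnalysisError("need at least 2 samples per class")
    return y


@dataclass
class ForestRunResult:
    """One forest's importance vector and its ranked top-20 list."""

    run_index: int
    seed: int
    importance: pd.Series  # per antigen
    top: pd.DataFrame  # columns antigen_id, rank_score; best first

    def __post_init__(self) -> None:
        k = len(self.top)
        expected = list(range(TOP_K, TOP_K - k, -1))
        if list(self.top["rank_score"]) != expected:
            raise AnalysisError("rank scores must run 20, 19, ... down the top list")


def _permutation_importance(
    model, X: np.ndarray, y: np.ndarray, n_repeats: int, rng: np.random.Generator
) -> np.ndarray:
    """Mean increase in MSE when one feature column is permuted at a time."""
    base = float(np.mean((model.predict(X) - y) ** 2))
    n, p = X.shape
    # one batched predict over all (feature, repeat) permutations
    blocks = np.tile(X, (p * n_repeats, 1, 1))
    for j in range(p):
        for r in range(n_repeats):
            blocks[j * n_repeats + r, :, j] = rng.permutation(X[:, j])
    pred = model.predict(blocks.reshape(p * n_repeats * n, p)).reshape(p * n_repeats, n)
    mse = np.mean((pred - y[None, :]) ** 2, axis=1)
    return mse.reshape(p, n_repeats).mean(axis=1) - base


def run_forest(
    features: pd.DataFrame,
    labels: pd.Series,
    n_trees: int = 500,
    mtry: int | None = None,
    seed: int = 0,
    mode: str = "regression",
    importance_repeats: int = 3,
    run_index: int = 0,
    top_k: int = TOP_K,
) -> ForestRunResult:
    """Fit one random forest and rank its top ``top_k`` antigens.

    ``mode='regression'`` (default) regresses the numeric 0/1 label and uses
    permutation importance; ``mode='classification'`` fits a classification
    forest and uses Gini importance. ``mtry`` defaults to ⌊√p⌋. Ties in
    importance are broken by the stable original antigen order.
    """
    if features.shape[1] < 2:
        raise AnalysisError("need at least 2 candidate antigens")
    y = _binary_labels(labels.reindex(features.index))
    X = features.to_numpy(float)
    p = X.shape[1]
    max_features = mtry if mtry is not None else max(1, int(np.sqrt(p)))

    if mode == "regression":
        model = RandomForestRegressor(
            n_estimators=n_trees, max_features=max_features, random_state=seed, n_jobs=1
        )
        model.fit(X, y)
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), 101)))
        imp = _permutation_importance(model, X, y, importance_repeats, rng)
    elif mode == "classification":
        model = RandomForestClassifier(
            n_estimators=n_trees, max_features=max_features, random_state=seed, n_jobs=1
        )
        model.fit(X, y.astype(int))
        imp = model.feature_importances_
    else:
        raise AnalysisError(f"unknown forest mode {mode!r}")

    importance = pd.Series(imp, index=features.columns, name="importance")
    order = np.argsort(-imp, kind="stable")[: min(top_k, p)]
    top = pd.DataFrame(
        {
            "antigen_id": features.columns[order],
            "rank_score": list(range(TOP_K, TOP_K - len(order), -1)),
        }
    )
    return ForestRunResult(run_index=run_index, seed=seed, importance=importance, top=top)


def run_forests(
    features: pd.DataFrame,
    labels: pd.Series,
    n_runs: int = 1000,
    master_seed: int = 0,
    **kwargs,
) -> list[ForestRunResult]:
    """Repeat :func:`run_forest` with per-run seeds derived from a master seed."""
    return [
        run_forest(
            features,
            labels,
            seed=stage_seed(master_seed, "forest", counter=i),
            run_index=i,
            **kwargs,
        )
        for i in range(n_runs)
    ]


@dataclass
class RankAggregation:
    """Aggregated top-20 membership over repeated forest runs.

    ``table``: per antigen appearing in at least one top list —
    inclusion_proportion (fraction of runs), average_rank_score (mean rank
    score over the runs where included) and weighted_mean_rank (their
    product), sorted by descending WMR with ties broken by antigen id.
    """

    table: pd.DataFrame
    n_runs: int

    def __post_init__(self) -> None:
        t = self.table
        if ((t["inclusion_proportion"] <= 0) | (t["inclusion_proportion"] > 1)).any():
            raise AnalysisError("inclusion proportions must lie in (0, 1]")
        if ((t["average_rank_score"] < 1) | (t["average_rank_score"] > TOP_K)).any():
            raise AnalysisError("average rank scores must lie in [1, 20]")


def aggregate_runs(runs: list[ForestRunResult]) -> RankAggregation:
    """Tally inclusion proportions, average rank scores and WMR over runs."""
    if not runs:
        raise AnalysisError("need at least one forest run to aggregate")
    n_runs = len(runs)
    stacked = pd.concat([r.top for r in runs], ignore_index=True)
    grouped = stacked.groupby("antigen_id")["rank_score"]
    table = pd.DataFrame(
        {
            "inclusion_proportion": grouped.size() / n_runs,
            "average_rank_score": grouped.mean(),
        }
    )
    table["weighted_mean_rank"] = table["inclusion_proportion"] * table["average_rank_score"]
    order = np.lexsort((table.index.astype(str), -table["weighted_mean_rank"].to_numpy()))
    table = table.iloc[order]
    table.index.name = "antigen_id"
    return RankAggregation(table=table, n_runs=n_runs)


def select_stage2_features(aggregation: RankAggregation, rule: str = "union", m: int | None = None) -> list[str]:
    """Reduce to the stage-2 antigen list.

    ``rule='union'`` (default): every antigen that appeared in any top-20
    list, in descending WMR order. ``rule='top'``: the ``m`` highest-WMR
    antigens.
    """
    if len(aggregation.table) == 0:
        raise AnalysisError("empty rank aggregation")
    ids = list(aggregation.table.index)
    if rule == "union":
        return ids
    if rule == "top":
        if m is None:
            raise AnalysisError("rule='top' requires m")
        return ids[:m]
    raise AnalysisError(f"unknown stage-2 rule {rule!r}")


@dataclass
class PanelModel:
    """Fitted pruned classification tree and the derived marker panel."""

    tree: DecisionTreeClassifier
    panel: list[str]
    feature_names: list[str]
    ccp_alpha: float
    per_sample_prob: pd.Series
    tree_sensitivity: float
    tree_specificity: float
    tree_auc: float
    anypos_sensitivity: float | None = None
    anypos_specificity: float | None = None
    anypos_auc: float | None = None
    cumulative: pd.DataFrame | None = None
    metadata: dict = field(default_factory=dict)


def _tree_panel(tree: DecisionTreeClassifier, feature_names: list[str]) -> list[str]:
    """Distinct split features in first-use (pre-order node index) order."""
    feats = tree.tree_.feature
    panel: list[str] = []
    for f in feats:
        if f >= 0 and feature_names[f] not in panel:
            panel.append(feature_names[f])
    return panel


def _sens_spec(predicted_patient: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    pos, neg = y == 1, y == 0
    sens = float(predicted_patient[pos].mean()) if pos.any() else float("nan")
    spec = float((~predicted_patient[neg]).mean()) if neg.any() else float("nan")
    return sens, spec


def fit_panel_tree(
    features: pd.DataFrame,
    labels: pd.Series,
    max_panel_size: int = 10,
    cv_folds: int = 10,
    seed: int = 0,
    calls: SeroCalls | None = None,
    prune_rule: str = "cap",
) -> PanelModel:
    """Grow and prune a CART tree; extract the marker panel.

    The tree is grown fully, then pruned along its cost-complexity path.
    ``prune_rule`` selects the pruning level:

    * ``'cap'`` (default): the largest tree on the path whose distinct split
      antigens number at most ``max_panel_size``. The tree here is a marker
      *selector* feeding the any-positive decision rule, not the deployed
      classifier; the forest stage has already screened the features, so the
      panel is taken as large as the cap allows — a combination of at most
      ``max_panel_size`` markers.
    * ``'1se'``: cross-validated 1-SE rule — the largest penalty whose mean
      CV accuracy is within one standard error of the best (stratified
      folds), for a parsimonious tree-rule classifier.
    * ``'min'``: the penalty with the best mean CV accuracy.

    Under ``'1se'``/``'min'`` the cap is enforced afterwards by applying
    larger penalties from the path until the panel fits. If ``calls`` is
    given, any-positive-rule metrics and the cumulative panel table are
    filled in.
    """
    from .evaluation import roc_auc  # local import to avoid a cycle

    if features.shape[1] < 1:
        raise AnalysisError("stage-2 antigen list is empty")
    if prune_rule not in ("cap", "1se", "min"):
        raise AnalysisError(f"unknown prune_rule {prune_rule!r}")
    y = _binary_labels(labels.reindex(features.index))
    X = features.to_numpy(float)
    if np.all(X == X[0, :], axis=0).all():
        raise AnalysisError("all features constant; no split possible")

    base = DecisionTreeClassifier(random_state=seed)
    path = base.cost_complexity_pruning_path(X, y)
    alphas = np.unique(np.clip(path.ccp_alphas, 0.0, None))
    feature_names = list(features.columns)

    def fitted(idx: int) -> DecisionTreeClassifier:
        t = DecisionTreeClassifier(random_state=seed, ccp_alpha=float(alphas[idx]))
        t.fit(X, y)
        return t

    if prune_rule == "cap":
        chosen_idx = 0
        tree = fitted(chosen_idx)
        panel = _tree_panel(tree, feature_names)
        while len(panel) > max_panel_size and chosen_idx + 1 < len(alphas):
            chosen_idx += 1
            tree = fitted(chosen_idx)
            panel = _tree_panel(tree, feature_names)
    else:
        n_min_class = int(min((y == 1).sum(), (y == 0).sum()))
        n_splits = max(2, min(cv_folds, n_min_class))
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        folds = list(skf.split(X, y))
        means, ses = [], []
        for a in alphas:
            accs = []
            for tr, te in folds:
                t = DecisionTreeClassifier(random_state=seed, ccp_alpha=float(a))
                t.fit(X[tr], y[tr])
                accs.append(float((t.predict(X[te]) == y[te]).mean()))
            accs = np.asarray(accs)
            means.append(accs.mean())
            ses.append(accs.std(ddof=1) / np.sqrt(len(accs)) if len(accs) > 1 else 0.0)
        means, ses = np.asarray(means), np.asarray(ses)
        best = int(np.argmax(means))
        if prune_rule == "min":
            chosen_idx = best
        else:
            threshold = means[best] - ses[best]
            chosen_idx = int(np.nonzero(means >= threshold)[0][-1])
        tree = fitted(chosen_idx)
        panel = _tree_panel(tree, feature_names)
        while len(panel) > max_panel_size and chosen_idx + 1 < len(alphas):
            chosen_idx += 1
            tree = fitted(chosen_idx)
            panel = _tree_panel(tree, feature_names)

    while tree.get_n_leaves() < 2 and chosen_idx > 0:
        chosen_idx -= 1
        tree = fitted(chosen_idx)
        panel = _tree_panel(tree, feature_names)
    if tree.get_n_leaves() < 2:
        raise AnalysisError("pruning produced a split-free tree even at zero penalty")
    if len(panel) > max_panel_size:
        raise AnalysisError("could not prune the tree below the panel cap")

    prob = tree.predict_proba(X)[:, 1]
    predicted = prob > 0.5
    sens, spec = _sens_spec(predicted, y)
    auc = roc_auc(pd.Series(prob, index=features.index), labels.reindex(features.index)).auc

    model = PanelModel(
        tree=tree,
        panel=panel,
        feature_names=feature_names,
        ccp_alpha=float(alphas[chosen_idx]),
        per_sample_prob=pd.Series(prob, index=features.index, name="p_patient"),
        tree_sensitivity=sens,
        tree_specificity=spec,
        tree_auc=auc,
        metadata={
            "prune_rule": prune_rule,
            "n_alphas": int(len(alphas)),
            "seed": int(seed),
            "max_panel_size": int(max_panel_size),
        },
    )

    if calls is not None and panel:
        pred = any_positive_classify(calls, panel)
        aligned = pred.reindex(features.index)
        p_patient = (aligned["predicted"] == "patient").to_numpy()
        model.anypos_sensitivity, model.anypos_specificity = _sens_spec(p_patient, y)
        model.anypos_auc = roc_auc(
            aligned["n_panel_positive"], labels.reindex(features.index)
        ).auc
        model.cumulative = cumulative_panel_metrics(calls, labels, panel)
    return model


def any_positive_classify(calls: SeroCalls, panel: list[str]) -> pd.DataFrame:
    """Call a sample a patient iff it is positive for ≥1 panel antigen.

    Returns a DataFrame with ``n_panel_positive`` (an integer score usable
    for ROC analysis) and the ``predicted`` label.
    """
    if not panel:
        raise AnalysisError("empty panel")
    missing = [a for a in panel if a not in calls.positive.columns]
    if missing:
        raise AnalysisError(f"panel antigen(s) not in calls: {missing}")
    n_pos = calls.positive[panel].sum(axis=1).astype(int)
    predicted = np.where(n_pos >= 1, "patient", "control")
    return pd.DataFrame({"n_panel_positive": n_pos, "predicted": predicted}, index=calls.positive.index)


def cumulative_panel_metrics(
    calls: SeroCalls, labels: pd.Series, panel: list[str]
) -> pd.DataFrame:
    """Any-positive sensitivity/specificity using the first k panel markers.

    Sensitivity is non-decreasing and specificity non-increasing in k: adding
    a marker can only add positive calls.
    """
    if not panel:
        raise AnalysisError("empty panel")
    labels = labels.reindex(calls.positive.index)
    y = (labels.to_numpy() == "patient")
    rows = []
    for k in range(1, len(panel) + 1):
        pred = calls.positive[panel[:k]].any(axis=1).to_numpy()
        sens = float(pred[y].mean()) if y.any() else float("nan")
        spec = float((~pred[~y]).mean()) if (~y).any() else float("nan")
        rows.append({"k": k, "marker": panel[k - 1], "sensitivity": sens, "specificity": spec})
    return pd.DataFrame(rows).set_index("k")
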