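"""Cutoffs, dichotomization, biomarker scores, serum scores, breadth."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import seropanel as sp
from seropanel.errors import AnalysisError
from conftest import random_matrix


def naive_biomarker_scores(positive: pd.DataFrame, sc: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Independent double-loop implementation of the per-antigen scores."""
    rows = {}
    for antigen in positive.columns:
        row = {}
        for cohort in ("patient", "control"):
            n_pos, ratios = 0, []
            for sample in positive.index:
                if labels[sample] != cohort:
                    continue
                if positive.loc[sample, antigen]:
                    n_pos += 1
                    ratios.append(sc.loc[sample, antigen])
            mean_sc = sum(ratios) / len(ratios) if ratios else 0.0
            row[f"n_pos_{cohort}"] = n_pos
            row[f"mean_sc_{cohort}"] = mean_sc
            row[f"score_{cohort}"] = n_pos * mean_sc ** (1.0 / 3.0)
        row["score_diff"] = row["score_patient"] - row["score_control"]
        rows[antigen] = row
    return pd.DataFrame.from_dict(rows, orient="index")


class TestComputeCutoffs:
    def test_one_to_eight_gives_fifteen(self):
        """{1..8}: Q75 = 6.25, IQR = 3.5 under linear interpolation, so the
        cutoff lands at 6.25 + 2.5 x 3.5 = 15.0."""
        rng = np.random.default_rng(0)
        m = random_matrix(rng, 8, 2)
        m.values.iloc[:, 0] = np.arange(1.0, 9.0)
        table = sp.compute_cutoffs(m).table
        assert table.loc["A0", "q75"] == pytest.approx(6.25)
        assert table.loc["A0", "iqr"] == pytest.approx(3.5)
        assert table.loc["A0", "cutoff"] == pytest.approx(15.0)

    def test_constant_antigen_cutoff_is_value(self):
        rng = np.random.default_rng(1)
        m = random_matrix(rng, 6, 2)
        m.values.iloc[:, 1] = 4.2
        table = sp.compute_cutoffs(m).table
        assert table.loc["A1", "iqr"] == 0.0
        assert table.loc["A1", "cutoff"] == pytest.approx(4.2)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(2)
        m = random_matrix(rng, 12, 6)
        scaled = m.copy()
        scaled.values = m.values * 3.7
        c1 = sp.compute_cutoffs(m).cutoffs
        c2 = sp.compute_cutoffs(scaled).cutoffs
        assert np.allclose(c2, c1 * 3.7)

    def test_controls_basis_uses_only_controls(self):
        rng = np.random.default_rng(3)
        m = random_matrix(rng, 12, 4, n_patients=6)
        ctl = sp.compute_cutoffs(m, basis="controls")
        manual = np.percentile(
            m.values.loc[m.labels == "control"].to_numpy(), 75, axis=0
        ) + 2.5 * (
            np.percentile(m.values.loc[m.labels == "control"], 75, axis=0)
            - np.percentile(m.values.loc[m.labels == "control"], 25, axis=0)
        )
        assert np.allclose(ctl.cutoffs, manual)
        assert ctl.basis == "controls"

    def test_too_few_basis_samples_errors(self):
        rng = np.random.default_rng(4)
        m = random_matrix(rng, 5, 3, n_patients=3)
        with pytest.raises(AnalysisError):
            sp.compute_cutoffs(m, basis="controls")


class TestDichotomize:
    def test_strict_inequality_and_sc_ratio(self):
        rng = np.random.default_rng(0)
        m = random_matrix(rng, 5, 2)
        cut = sp.compute_cutoffs(m)
        cut.table.loc[:, "cutoff"] = 15.0
        m.values.iloc[0, 0] = 30.0  # positive, S/C = 2
        m.values.iloc[1, 0] = 15.0  # exactly at the cutoff: negative
        calls = sp.dichotomize(m, cut)
        assert calls.positive.iloc[0, 0]
        assert calls.sc_ratio.iloc[0, 0] == pytest.approx(2.0)
        assert not calls.positive.iloc[1, 0]
        assert np.isnan(calls.sc_ratio.iloc[1, 0])

    def test_missing_cutoff_errors(self):
        rng = np.random.default_rng(1)
        m = random_matrix(rng, 5, 3)
        cut = sp.compute_cutoffs(m)
        cut.table.drop(index="A1", inplace=True)
        with pytest.raises(AnalysisError, match="A1"):
            sp.dichotomize(m, cut)

    def test_nonpositive_cutoff_antigen_excluded_with_warning(self):
        rng = np.random.default_rng(2)
        m = random_matrix(rng, 6, 3)
        m.values.iloc[:, 2] = 0.0
        cut = sp.compute_cutoffs(m)
        with pytest.warns(UserWarning, match="non-positive cutoff"):
            calls = sp.dichotomize(m, cut)
        assert "A2" in calls.unscorable
        assert "A2" not in calls.positive.columns

    def test_null_positive_fraction_matches_monte_carlo_tail(self):
        """On unplanted lognormal data, the per-antigen positive fraction
        matches the tail mass beyond Q75 + 2.5 x IQR estimated by a large
        independent Monte-Carlo draw from the same distribution."""
        rng = np.random.default_rng(3)
        big = np.exp(rng.normal(0.0, 1.0, 200_000))
        cutoff = np.percentile(big, 75) + 2.5 * (
            np.percentile(big, 75) - np.percentile(big, 25)
        )
        expected_tail = (big > cutoff).mean()

        m = random_matrix(rng, 400, 50)
        calls = sp.dichotomize(m, sp.compute_cutoffs(m))
        observed = calls.positive.to_numpy().mean()
        assert observed == pytest.approx(expected_tail, rel=0.35)


class TestBiomarkerScores:
    def test_direct_arithmetic_examples(self):
        rng = np.random.default_rng(0)
        m = random_matrix(rng, 16, 2, n_patients=8)
        cut = sp.compute_cutoffs(m)
        cut.table.loc[:, "cutoff"] = 1.0
        # antigen A0: all 8 patients positive with S/C = 8, no controls positive
        m.values.loc[:, "A0"] = 0.5
        m.values.loc[m.labels == "patient", "A0"] = 8.0
        # antigen A1: 3 patient positives with S/C {2, 2, 16}
        m.values.loc[:, "A1"] = 0.5
        m.values.loc[["S0", "S1", "S2"], "A1"] = [2.0, 2.0, 16.0]
        calls = sp.dichotomize(m, cut)
        table = sp.biomarker_scores(calls, m.labels)
        assert table.loc["A0", "score_patient"] == pytest.approx(16.0)  # 8 x 8^(1/3)
        assert table.loc["A0", "score_control"] == 0.0
        assert table.loc["A0", "score_diff"] == pytest.approx(16.0)
        assert table.loc["A1", "score_patient"] == pytest.approx(3 * (20 / 3) ** (1 / 3))
        assert table.loc["A1", "sensitivity"] == pytest.approx(3 / 8)
        assert table.loc["A1", "specificity"] == 1.0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_matches_naive_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        m = random_matrix(rng, 30, 20)
        calls = sp.dichotomize(m, sp.compute_cutoffs(m))
        table = sp.biomarker_scores(calls, m.labels)
        naive = naive_biomarker_scores(calls.positive, calls.sc_ratio, m.labels)
        for col in ("n_pos_patient", "n_pos_control", "score_patient", "score_control", "score_diff"):
            assert np.allclose(table[col], naive.loc[table.index, col])

    def test_cohort_swap_negates_score_diff(self):
        rng = np.random.default_rng(5)
        m = random_matrix(rng, 20, 10, n_patients=10)
        calls = sp.dichotomize(m, sp.compute_cutoffs(m))
        t1 = sp.biomarker_scores(calls, m.labels)
        swapped = m.labels.map({"patient": "control", "control": "patient"})
        t2 = sp.biomarker_scores(calls, swapped)
        assert np.allclose(t1["score_diff"], -t2["score_diff"])

    def test_raising_positive_intensity_never_decreases_patient_score(self):
        rng = np.random.default_rng(6)
        m = random_matrix(rng, 20, 5)
        cut = sp.compute_cutoffs(m)
        calls = sp.dichotomize(m, cut)
        base = sp.biomarker_scores(calls, m.labels)
        # raise one patient-positive intensity, keeping the cutoffs frozen
        pos_patients = calls.positive.loc[m.labels == "patient"]
        antigen = pos_patients.sum().idxmax()
        sample = pos_patients.index[pos_patients[antigen]][0]
        m2 = m.copy()
        m2.values.loc[sample, antigen] *= 5.0
        t2 = sp.biomarker_scores(sp.dichotomize(m2, cut), m.labels)
        assert t2.loc[antigen, "score_patient"] >= base.loc[antigen, "score_patient"]
        assert t2.loc[antigen, "score_diff"] >= base.loc[antigen, "score_diff"]

    def test_bad_label_errors(self):
        rng = np.random.default_rng(7)
        m = random_matrix(rng, 6, 3)
        calls = sp.dichotomize(m, sp.compute_cutoffs(m))
        labels = m.labels.copy()
        labels.iloc[0] = "unknown"
        with pytest.raises(AnalysisError):
            sp.biomarker_scores(calls, labels)


class TestSelectCandidates:
    def _table(self, diffs):
        return pd.DataFrame(
            {"score_diff": diffs}, index=[f"A{i}" for i in range(len(diffs))]
        )

    def test_strict_threshold(self):
        assert sp.select_candidates(self._table([6.0, 5.0, 4.9]), threshold=5) == ["A0"]

    def test_no_filter_returns_rank_order(self):
        got = sp.select_candidates(self._table([1.0, 3.0, 2.0]), threshold=-np.inf)
        assert got == ["A1", "A2", "A0"]

    def test_ties_broken_by_antigen_id(self):
        got = sp.select_candidates(self._table([2.0, 2.0, 3.0]), threshold=0)
        assert got == ["A2", "A0", "A1"]

    def test_recovers_planted_antigens(self, calls_and_scores):
        _, _, scores, _, truth = calls_and_scores
        selected = sp.select_candidates(scores, threshold=5)
        planted = set(truth.planted_antigen_ids)
        assert len(planted & set(selected)) >= 12


class TestSerumScores:
    def test_definition_and_empty_sum(self):
        rng = np.random.default_rng(0)
        m = random_matrix(rng, 4, 2)
        m.values.iloc[0] = [20.0, 5.0]
        m.values.iloc[1:] = 1.0
        cut = sp.compute_cutoffs(m)
        cut.table.loc[:, "cutoff"] = 10.0
        res = sp.serum_scores(m, cut)
        assert res.per_sample.loc["S0", "serum_score"] == 20.0  # full intensity, not excess
        assert res.per_sample.loc["S0", "n_positive"] == 1
        assert res.per_sample.loc["S1", "serum_score"] == 0.0
        assert res.per_sample.loc["S1", "n_positive"] == 0

    def test_empty_subset_errors(self):
        rng = np.random.default_rng(1)
        m = random_matrix(rng, 4, 3)
        with pytest.raises(AnalysisError):
            sp.serum_scores(m, sp.compute_cutoffs(m), subset=[])

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_additivity_over_disjoint_subsets(self, seed):
        rng = np.random.default_rng(seed)
        m = random_matrix(rng, 10, 8)
        cut = sp.compute_cutoffs(m)
        a, b = ["A0", "A1", "A2"], ["A5", "A7"]
        sa = sp.serum_scores(m, cut, subset=a).per_sample["serum_score"]
        sb = sp.serum_scores(m, cut, subset=b).per_sample["serum_score"]
        sab = sp.serum_scores(m, cut, subset=a + b).per_sample["serum_score"]
        assert np.allclose(sab, sa + sb)

    def test_subset_restriction_never_increases_score(self):
        rng = np.random.default_rng(2)
        m = random_matrix(rng, 10, 8)
        cut = sp.compute_cutoffs(m)
        full = sp.serum_scores(m, cut).per_sample["serum_score"]
        sub = sp.serum_scores(m, cut, subset=["A0", "A1"]).per_sample["serum_score"]
        assert (sub <= full + 1e-12).all()

    def test_patient_scores_exceed_controls_on_planted_cohort(self, calls_and_scores):
        cutoffs, _, scores, matrix, truth = calls_and_scores
        res = sp.serum_scores(matrix, cutoffs, subset=truth.planted_antigen_ids)
        assert (
            res.summary.loc["patient", "serum_score_median"]
            > res.summary.loc["control", "serum_score_median"]
        )


class TestBreadthSummary:
    def test_all_negative_and_conservation(self):
        rng = np.random.default_rng(0)
        m = random_matrix(rng, 6, 4)
        cut = sp.compute_cutoffs(m)
        cut.table.loc[:, "cutoff"] = np.inf
        calls = sp.dichotomize(m, cut)
        summary = sp.breadth_summary(calls, m.labels)
        assert (summary["median"] == 0).all()
        assert summary["total_positive"].sum() == 0

    def test_counts_match_grand_total(self, calls_and_scores):
        _, calls, _, matrix, _ = calls_and_scores
        subset = list(calls.positive.columns[:50])
        summary = sp.breadth_summary(calls, matrix.labels, subset=subset)
        assert summary["total_positive"].sum() == int(calls.positive[subset].to_numpy().sum())

    def test_single_sample_count(self):
        rng = np.random.default_rng(1)
        m = random_matrix(rng, 4, 5)
        cut = sp.compute_cutoffs(m)
        cut.table.loc[:, "cutoff"] = 0.5
        m.values.iloc[0] = [1.0, 1.0, 1.0, 0.1, 0.1]
        calls = sp.dichotomize(m, cut)
        assert int(calls.positive.iloc[0].sum()) == 3
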