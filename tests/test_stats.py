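"""Hypothesis tests, FDR control, ROC operating points and bootstrap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acctex.stats import (
    auc_mann_whitney,
    bh_adjust,
    bootstrap_ci,
    chi_square,
    dunn_posthoc,
    kruskal_wallis,
    mann_whitney,
    ppv_npv,
    roc_youden,
    run_grade_analysis,
    run_variant_analysis,
)
from acctex.synthetic import CohortSpec, generate_cohort_features
from oracles import (
    auc_by_concordance,
    bh_step_up,
    dunn_z_transcription,
    exact_mwu_pvalue,
    kruskal_h_transcription,
)


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        """{1,2,3} vs {4,5,6}: U = 0 for the first group, exact p = 2/20."""
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)
        assert "exact" in res.test

    def test_two_vs_two(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.p_value == pytest.approx(1 / 3)

    def test_identical_groups_p_one(self):
        res = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(5):
            x = rng.normal(size=4).round(2)
            y = rng.normal(size=5).round(2) + 0.5
            if np.unique(np.concatenate([x, y])).size < 9:
                continue
            assert mann_whitney(x, y).p_value == pytest.approx(exact_mwu_pvalue(x, y))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestKruskalDunnChi:
    def test_identical_groups(self):
        res = kruskal_wallis([[1, 2], [1, 2], [1, 2]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_rank_formula(self):
        groups = [[1, 2], [3, 4], [5, 6]]
        res = kruskal_wallis(groups)
        assert res.statistic == pytest.approx(kruskal_h_transcription(groups))

    def test_group_order_symmetry(self, rng):
        gs = [rng.normal(size=5), rng.normal(size=6), rng.normal(size=4)]
        a = kruskal_wallis(gs)
        b = kruskal_wallis(gs[::-1])
        assert a.statistic == pytest.approx(b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_dunn_identical_groups(self):
        res = dunn_posthoc({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
        assert all(r.p_value == pytest.approx(1.0) for r in res)

    def test_dunn_separated_pair_smallest_p(self, rng):
        groups = {
            "a": rng.normal(0, 1, 8),
            "b": rng.normal(0.3, 1, 8),
            "c": rng.normal(8.0, 1, 8),
        }
        res = {(r.group_a, r.group_b): r.p_value for r in dunn_posthoc(groups)}
        assert res[("a", "c")] == min(res.values())

    def test_dunn_matches_transcription(self, rng):
        groups = {
            "x": rng.integers(0, 6, 7).astype(float),  # ties on purpose
            "y": rng.integers(2, 8, 6).astype(float),
            "z": rng.integers(0, 9, 8).astype(float),
        }
        ours = {(r.group_a, r.group_b): r.z for r in dunn_posthoc(groups)}
        ref = dunn_z_transcription(groups)
        for pair, z in ref.items():
            assert ours[pair] == pytest.approx(z, abs=1e-10)

    def test_chi_square_examples(self):
        assert chi_square([[5, 5], [5, 5]]).statistic == pytest.approx(0.0)
        assert chi_square([[5, 5], [5, 5]]).p_value == pytest.approx(1.0)
        res = chi_square([[10, 0], [0, 10]])
        assert res.statistic == pytest.approx(20.0)  # no continuity correction
        assert res.statistic >= 0.0


class TestBhAdjust:
    def test_worked_example(self):
        adj = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    def test_matches_step_up_transcription_and_monotone(self, pvals):
        adj = bh_adjust(pvals)
        np.testing.assert_allclose(adj, bh_step_up(pvals), atol=1e-12)
        assert np.all(adj >= np.asarray(pvals) - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)


class TestRoc:
    def test_perfect_separation(self):
        res = roc_youden([0.9, 0.8, 0.1, 0.2], ["h", "h", "l", "l"], "h", n_boot=50, seed=0)
        assert res.auc == 1.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        assert res.ppv == 1.0 and res.npv == 1.0
        for lo, hi in res.ci.values():
            assert lo <= hi

    def test_auc_equals_u_statistic_identity(self, rng):
        for _ in range(10):
            scores = rng.normal(size=24)
            labels = rng.choice(["h", "l"], size=24)
            if len(set(labels)) < 2:
                continue
            assert auc_mann_whitney(scores, labels, "h") == pytest.approx(
                auc_by_concordance(scores, labels, "h")
            )

    def test_independent_labels_auc_near_half(self, rng):
        scores = rng.normal(size=2000)
        labels = rng.choice(["h", "l"], size=2000)
        assert auc_mann_whitney(scores, labels, "h") == pytest.approx(0.5, abs=0.05)

    def test_direction_flips_with_effect_sign(self, rng):
        lo = rng.normal(0, 1, 15)
        hi = rng.normal(3, 1, 15)
        scores = np.concatenate([lo, hi])
        labels = np.array(["l"] * 15 + ["h"] * 15)
        up = roc_youden(scores, labels, "h", n_boot=0)
        down = roc_youden(-scores, labels, "h", n_boot=0)
        assert up.direction == ">" and down.direction == "<"
        assert up.auc == pytest.approx(down.auc)

    def test_bootstrap_ci_reproducible_and_brackets_point(self, rng):
        scores = np.concatenate([rng.normal(0, 1, 14), rng.normal(1.5, 1, 14)])
        labels = np.array(["l"] * 14 + ["h"] * 14)
        a = roc_youden(scores, labels, "h", n_boot=200, seed=42)
        b = roc_youden(scores, labels, "h", n_boot=200, seed=42)
        assert a.ci == b.ci
        lo, hi = a.ci["auc"]
        assert lo <= a.auc <= hi


class TestPpvNpv:
    def test_perfect_specificity_forces_ppv_one(self):
        for sens in (0.2, 0.667, 1.0):
            for prev in (0.1, 0.48, 0.9):
                ppv, _ = ppv_npv(sens, 1.0, prev)
                assert ppv == 1.0

    def test_uninformative_test_gives_prevalence(self):
        ppv, npv = ppv_npv(0.5, 0.5, 0.3)
        assert ppv == pytest.approx(0.3)
        assert npv == pytest.approx(0.7)


class TestBootstrapCi:
    def test_constant_statistic_zero_width(self):
        lo, hi = bootstrap_ci(np.ones(20), np.mean, n_boot=100, seed=1)
        assert lo == hi == 1.0

    def test_same_seed_identical(self, rng):
        data = rng.normal(size=30)
        assert bootstrap_ci(data, np.mean, seed=9) == bootstrap_ci(data, np.mean, seed=9)

    def test_coverage_of_true_mean(self):
        """Percentile CI for a normal mean covers the truth ~95% of the time."""
        rng = np.random.default_rng(2024)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            data = rng.normal(0.0, 1.0, 40)
            lo, hi = bootstrap_ci(data, np.mean, n_boot=300,
                                  seed=int(rng.integers(2**31)))
            hits += lo <= 0.0 <= hi
        assert hits / n_rep == pytest.approx(0.95, abs=0.05)


class TestAnalysisArms:
    def test_planted_effect_recovered(self):
        table, truth = generate_cohort_features(CohortSpec(seed=5))
        res = run_grade_analysis(table, n_boot=50, seed=5)
        sel = res.selection[("tumour-vital", "venous")]
        sig = set(res.tests[res.tests.significant].feature)
        reps = {sel.representative("firstorder_Skewness")}
        assert reps & sig, f"skewness representative {reps} not in {sig}"
        assert not res.roc.empty

    def test_label_permutation_mostly_empty(self):
        from acctex.synthetic import null_cohort_spec

        empty = 0
        for s in range(20):
            table, _ = generate_cohort_features(null_cohort_spec(seed=1000 + s))
            res = run_grade_analysis(table, n_boot=0, seed=s)
            empty += int(res.tests.significant.sum() == 0)
        assert empty >= 17  # pipeline-level type-I control (spot check)

    def test_variant_arm_runs_dunn_on_raw_hits(self):
        spec = CohortSpec(
            n_per_group={"conventional": 10, "oncocytic": 9, "myxoid": 7},
            features={
                "gldm_DependenceVariance": {
                    "conventional": (0.45, 0.10),
                    "myxoid": (0.50, 0.05),
                    "oncocytic": (0.20, 0.08),
                }
            },
            n_null_features=5,
            n_collinear_pairs=0,
            label_column="variant",
            seed=11,
        )
        table, _ = generate_cohort_features(spec)
        res = run_variant_analysis(table)
        assert (res.tests.test == "kruskal-wallis").all()
        assert res.posthoc is not None and not res.posthoc.empty
        pairs = set(map(tuple, res.posthoc[["group_a", "group_b"]].to_numpy()))
        assert len(pairs) == 3

    def test_empty_table_is_clean_error(self):
        with pytest.raises(ValueError, match="empty"):
            run_grade_analysis(pd.DataFrame())

    def test_too_small_groups_skipped(self):
        table, _ = generate_cohort_features(
            CohortSpec(n_per_group={"low": 2, "high": 2}, seed=3)
        )
        table = table[~((table.grade == "high") & (table.case_id != "high000"))]
        res = run_grade_analysis(table, n_boot=0)
        assert res.tests.empty
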