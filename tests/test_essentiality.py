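"""Knockout classification, depth summaries, t tests, core region, copy ratios."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from virogenescape.ancestry import AncestryAssignment
from virogenescape.essentiality import (
    classify_essential,
    copy_ratio_5p_3p,
    core_region,
    depth_phenotype_summary,
    two_sample_t,
)


def _records(yields, clonable=None, viable=None):
    n = len(yields)
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n)],
            "relative_yield": yields,
            "ko_clonable": pd.array(
                clonable if clonable is not None else [pd.NA] * n, dtype="boolean"
            ),
            "large_deletion_viable": pd.array(
                viable if viable is not None else [pd.NA] * n, dtype="boolean"
            ),
        }
    )


class TestClassifyEssential:
    def test_yield_rule(self):
        df = classify_essential(_records([0.005, 1.0]), tau=0.01, rule="yield")
        assert df["essential"].tolist() == [True, False]

    def test_mixed_toy_table_matches_row_oracle(self):
        yields = [0.0, 0.009, 0.01, 0.5, 1.0, 2.3]
        df = classify_essential(_records(yields), tau=0.01, rule="yield")
        assert df["essential"].tolist() == [y < 0.01 for y in yields]

    def test_clonability_rule(self):
        df = classify_essential(
            _records([0.5, 0.5], clonable=[False, True]), rule="clonability"
        )
        assert df["essential"].tolist() == [True, False]

    def test_combined_rule(self):
        df = classify_essential(
            _records([0.001, 0.001, 0.9], clonable=[False, True, False]),
            tau=0.01,
            rule="combined",
        )
        assert df["essential"].tolist() == [True, False, False]

    def test_clonability_missing_flags_lists_genes(self):
        with pytest.raises(ValueError, match="g1"):
            classify_essential(
                _records([0.5, 0.5], clonable=[True, pd.NA]), rule="clonability"
            )

    @pytest.mark.parametrize("tau", [0.0, -1, 1.5])
    def test_invalid_tau_rejected(self, tau):
        with pytest.raises(ValueError):
            classify_essential(_records([0.5]), tau=tau)


class TestTwoSampleT:
    def test_identical_samples(self):
        t, _, p = two_sample_t([1, 2, 3], [1, 2, 3])
        assert (t, p) == (0.0, 1.0)

    @pytest.mark.parametrize("variant", ["student", "welch"])
    def test_matches_independent_reference(self, variant):
        a = [0.1, 0.2, 0.15]
        b = [1.0, 1.1, 0.9]
        t, dof, p = two_sample_t(a, b, variant=variant)
        ref = stats.ttest_ind(a, b, equal_var=(variant == "student"))
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)
        if variant == "student":
            assert dof == 4

    @pytest.mark.parametrize("seed", range(10))
    def test_random_samples_match_reference(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, size=int(rng.integers(3, 30)))
        b = rng.normal(0.5, 2, size=int(rng.integers(3, 30)))
        for variant, equal_var in (("student", True), ("welch", False)):
            t, dof, p = two_sample_t(a, b, variant=variant)
            ref = stats.ttest_ind(a, b, equal_var=equal_var)
            assert t == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_student_equals_welch_for_balanced_equal_variance(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [2.0, 3.0, 4.0, 5.0]  # same variance, same n
        ts = two_sample_t(a, b, variant="student")
        tw = two_sample_t(a, b, variant="welch")
        assert ts[0] == pytest.approx(tw[0])
        assert ts[1] == pytest.approx(tw[1])  # Welch df reduces to n1+n2-2
        assert ts[2] == pytest.approx(tw[2])

    def test_zero_variance_unequal_means_degenerate(self):
        t, _, p = two_sample_t([1, 1, 1], [2, 2, 2])
        assert math.isinf(t) and p == 0.0

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            two_sample_t([1], [1, 2])


class TestDepthPhenotypeSummary:
    def _scores(self, mapping, S=5):
        return AncestryAssignment(focal="F", S=S, score=mapping)

    def test_group_median(self):
        recs = classify_essential(_records([0.2, 1.0, 0.6]), tau=0.01)
        scores = self._scores({"g0": 3, "g1": 3, "g2": 3})
        summary = depth_phenotype_summary(recs, scores)
        row = summary.per_category.set_index("category").loc[3]
        assert row["median_yield"] == pytest.approx(0.6)
        assert row["n"] == 3

    def test_all_essential_fraction_one(self):
        recs = classify_essential(_records([0.001] * 6), tau=0.01)
        scores = self._scores({f"g{i}": i % 3 for i in range(6)}, S=3)
        summary = depth_phenotype_summary(recs, scores)
        nonempty = summary.per_category[summary.per_category["n"] > 0]
        assert (nonempty["fraction_essential"] == 1.0).all()

    def test_counts_conserved_and_empty_categories_flagged(self):
        recs = classify_essential(_records([0.5] * 4), tau=0.01)
        scores = self._scores({f"g{i}": 5 for i in range(4)})
        summary = depth_phenotype_summary(recs, scores)
        assert summary.per_category["n"].sum() == 4
        assert summary.per_category.set_index("category").loc[2, "n"] == 0
        assert np.isnan(
            summary.per_category.set_index("category").loc[2, "median_yield"]
        )

    def test_pairwise_tests_have_bh_adjustment(self):
        rng = np.random.default_rng(0)
        n = 60
        cats = rng.integers(0, 3, size=n)
        recs = classify_essential(
            _records(list(rng.lognormal(0, 0.3, size=n))), tau=0.01
        )
        scores = self._scores({f"g{i}": int(c) for i, c in enumerate(cats)}, S=2)
        summary = depth_phenotype_summary(recs, scores)
        assert set(summary.pairwise.columns) >= {"cat_a", "cat_b", "t", "df", "p", "p_bh"}
        assert (summary.pairwise["p_bh"] >= summary.pairwise["p"] - 1e-12).all()

    def test_unscored_gene_rejected(self):
        recs = classify_essential(_records([0.5]), tau=0.01)
        with pytest.raises(ValueError, match="g0"):
            depth_phenotype_summary(recs, self._scores({}))


class TestCoreRegion:
    def test_min_max_interval(self):
        recs = _records([1.0] * 3, viable=[False, False, False])
        ords = {"g0": 100, "g1": 300, "g2": 544}
        assert core_region(recs, ords) == (100, 544)

    def test_single_locus(self):
        recs = _records([1.0], viable=[False])
        assert core_region(recs, {"g0": 77}) == (77, 77)

    def test_viable_loci_ignored(self):
        recs = _records([1.0] * 4, viable=[True, False, False, True])
        ords = {"g0": 1, "g1": 200, "g2": 300, "g3": 999}
        assert core_region(recs, ords) == (200, 300)

    def test_no_inviable_loci_rejected(self):
        recs = _records([1.0] * 2, viable=[True, True])
        with pytest.raises(ValueError, match="no core detected"):
            core_region(recs, {"g0": 1, "g1": 2})


class TestCopyRatio:
    @pytest.mark.parametrize("a,b,expect", [(100, 100, 1.0), (100, 50, 2.0)])
    def test_finite_ratios(self, a, b, expect):
        assert copy_ratio_5p_3p(a, b) == expect

    def test_complete_3p_loss_flagged_infinite(self):
        assert math.isinf(copy_ratio_5p_3p(100, 0))
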