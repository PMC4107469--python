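"""Subject grouping, Fisher exact test, BH adjustment, prevalence contrasts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from cnvpheno.association import (
    GROUP_COMMON_ONLY,
    GROUP_DE_NOVO,
    GROUP_FAMILIAL_ONLY,
    bh_adjust,
    fisher_exact_2x2,
    group_subjects,
    prevalence_comparison,
)
from cnvpheno.genomic import CnvClass, calls_by_subject
from cnvpheno.phenotypes import PhenotypeMatrix


class TestGroupSubjects:
    def test_definitions(self):
        grouping = group_subjects(
            {
                "a": [CnvClass.DE_NOVO, CnvClass.COMMON],
                "b": [CnvClass.FAMILIAL],
                "c": [CnvClass.COMMON],
                "d": [CnvClass.DE_NOVO, CnvClass.FAMILIAL],
                "e": [],
            }
        )
        assert grouping.group_of == {
            "a": GROUP_DE_NOVO, "b": GROUP_FAMILIAL_ONLY,
            "c": GROUP_COMMON_ONLY, "d": GROUP_DE_NOVO, "e": GROUP_COMMON_ONLY,
        }
        assert grouping.dual_carriers == frozenset({"d"})

    def test_unresolved_promotion_flag(self):
        classes = {"a": [CnvClass.UNIQUE_UNRESOLVED]}
        assert group_subjects(classes).group_of["a"] == GROUP_COMMON_ONLY
        promoted = group_subjects(classes, unresolved_as_familial=True)
        assert promoted.group_of["a"] == GROUP_FAMILIAL_ONLY

    def test_cohort_recovers_published_split(self, study, classified):
        """18 de novo carriers, 22 familial carriers with 2 dual -> 18/20/40."""
        grouping = group_subjects(
            calls_by_subject(study.calls, classified), subjects=study.matrix.subjects
        )
        assert grouping.sizes == {
            GROUP_DE_NOVO: 18, GROUP_FAMILIAL_ONLY: 20, GROUP_COMMON_ONLY: 40,
        }
        assert len(grouping.dual_carriers) == 2
        assert grouping.dual_carriers <= set(grouping.members(GROUP_DE_NOVO))


class TestFisherExact:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ([[3, 1], [1, 3]], 34 / 70),  # enumeration over X in 0..4
            ([[5, 0], [0, 5]], 2 / 252),  # only the two extreme tables qualify
            ([[0, 0], [4, 7]], 1.0),  # degenerate margin
            ([[2, 2], [2, 2]], 1.0),
        ],
    )
    def test_known_values(self, table, expected):
        assert fisher_exact_2x2(table) == pytest.approx(expected, rel=1e-12)

    def test_rejects_negative_and_non_integer(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, -1], [0, 2]])
        with pytest.raises(ValueError):
            fisher_exact_2x2(np.array([[0.5, 1], [1, 1]]))

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            table = rng.integers(0, 30, size=(2, 2))
            ours = fisher_exact_2x2(table)
            ref = sps.fisher_exact(table, alternative="two-sided").pvalue
            assert ours == pytest.approx(ref, rel=1e-7, abs=1e-12)


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        out = bh_adjust([0.01, 0.04, 0.03, 0.005])
        assert out == pytest.approx([0.02, 0.04, 0.04, 0.02])

    def test_ties_and_singleton(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])
        assert bh_adjust([0.123]) == pytest.approx([0.123])

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.random(rng.integers(1, 60))
            ref = multipletests(p, method="fdr_bh")[1]
            assert bh_adjust(p) == pytest.approx(ref, rel=1e-12)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        p = rng.random(25)
        perm = rng.permutation(25)
        assert bh_adjust(p)[perm] == pytest.approx(bh_adjust(p[perm]))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


def _grouped_matrix(n_a=20, n_b=20, n_features=10, seed=0):
    rng = np.random.default_rng(seed)
    subjects = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    values = rng.integers(0, 2, size=(n_a + n_b, n_features))
    matrix = PhenotypeMatrix(
        pd.DataFrame(values, index=subjects,
                     columns=[f"f{i}" for i in range(n_features)])
    )
    grouping = group_subjects(
        {s: [CnvClass.DE_NOVO] for s in subjects[:n_a]},
        subjects=subjects,
    )
    return matrix, grouping


class TestPrevalenceComparison:
    def test_equal_prevalence_gives_unit_p(self):
        matrix, grouping = _grouped_matrix(4, 4, 3, seed=1)
        matrix.data.iloc[:, :] = np.array([[1, 0, 1]] * 8, dtype=np.int8)
        table = prevalence_comparison(matrix, grouping)
        assert (table["p_value"] == 1.0).all()
        assert (table["q_value"] == 1.0).all()

    def test_planted_feature_attains_minimum_q(self):
        matrix, grouping = _grouped_matrix(20, 20, 10, seed=2)
        matrix.data["f0"] = [1] * 20 + [0] * 20  # all of A, none of B
        table = prevalence_comparison(matrix, grouping)
        assert table.loc["f0", "q_value"] == table["q_value"].min()
        assert table.loc["f0", "p_value"] < 1e-8

    def test_swapped_groups_preserve_pvalues(self):
        matrix, grouping = _grouped_matrix(15, 25, 8, seed=3)
        fwd = prevalence_comparison(matrix, grouping,
                                    (GROUP_DE_NOVO, GROUP_COMMON_ONLY))
        rev = prevalence_comparison(matrix, grouping,
                                    (GROUP_COMMON_ONLY, GROUP_DE_NOVO))
        assert fwd["p_value"].to_numpy() == pytest.approx(rev["p_value"].to_numpy())

    def test_exclusion_removes_subjects_from_both_columns(self):
        matrix, grouping = _grouped_matrix(10, 10, 4, seed=4)
        table = prevalence_comparison(matrix, grouping, exclude={"a0", "b0"})
        assert (table["n_a"] == 9).all() and (table["n_b"] == 9).all()

    def test_empty_group_after_exclusion_errors(self):
        matrix, grouping = _grouped_matrix(2, 2, 3, seed=5)
        with pytest.raises(ValueError, match="empty group"):
            prevalence_comparison(matrix, grouping, exclude={"a0", "a1"})

    def test_q_dominates_p(self, study):
        matrix = study.matrix
        grouping = group_subjects({}, subjects=matrix.subjects)
        # artificial split: first 30 subjects vs rest
        grouping = group_subjects(
            {s: [CnvClass.DE_NOVO] for s in matrix.subjects[:30]},
            subjects=matrix.subjects,
        )
        table = prevalence_comparison(matrix, grouping)
        assert (table["q_value"] >= table["p_value"] - 1e-12).all()
        assert (table["q_value"] <= 1.0).all()
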