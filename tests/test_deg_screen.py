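import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from moxatox.deg_screen import (
    DdctInput,
    ExpressionMatrix,
    ScreenCriteria,
    bh_fdr,
    ddct_relative_expression,
    differential_expression,
    log2_fold_change,
    screen_degs,
    welch_t_pvalues,
)
from moxatox.errors import ValidationError
from moxatox.synthetic import SpikeDesign, gen_expression_matrix


def matrix_from_rows(rows: dict, n_control: int, n_exposed: int) -> ExpressionMatrix:
    samples = [f"c{j}" for j in range(n_control)] + [f"e{j}" for j in range(n_exposed)]
    values = pd.DataFrame(rows, index=samples).T
    groups = pd.Series(
        ["control"] * n_control + ["exposed"] * n_exposed, index=samples
    )
    return ExpressionMatrix(values=values, groups=groups)


class TestLog2FoldChange:
    def test_exact_power_of_two(self):
        mat = matrix_from_rows({"g": [10, 10, 10, 43, 43, 43]}, 3, 3)
        assert log2_fold_change(mat, "g") == pytest.approx(2.0)  # log2(44/11)

    def test_equal_means_and_all_zero(self):
        mat = matrix_from_rows({"flat": [5, 5, 5, 5, 5, 5], "zero": [0] * 6}, 3, 3)
        assert log2_fold_change(mat, "flat") == 0.0
        assert log2_fold_change(mat, "zero") == 0.0  # pseudocount guards 0/0

    def test_antisymmetry_under_label_swap(self):
        mat = matrix_from_rows({"g": [10.0, 12.0, 8.0, 40.0, 44.0, 36.0]}, 3, 3)
        swapped = ExpressionMatrix(
            values=mat.values.copy(),
            groups=mat.groups.map({"control": "exposed", "exposed": "control"}),
        )
        assert log2_fold_change(swapped, "g") == pytest.approx(
            -log2_fold_change(mat, "g"), rel=1e-12
        )

    def test_missing_gene(self):
        mat = matrix_from_rows({"g": [1, 2, 3, 4, 5, 6]}, 3, 3)
        with pytest.raises(ValidationError, match="absent"):
            log2_fold_change(mat, "absent")


class TestWelch:
    def test_identical_groups_give_p_one(self):
        mat = matrix_from_rows({"g": [3.0, 3.0, 3.0, 3.0, 3.0, 3.0]}, 3, 3)
        assert welch_t_pvalues(mat)["g"] == 1.0

    def test_small_sample_example(self):
        # t = -1.2247, Welch-Satterthwaite df = 4; p frozen from the
        # regularized incomplete beta form of the t CDF
        mat = matrix_from_rows({"g": [1.0, 2.0, 3.0, 2.0, 3.0, 4.0]}, 3, 3)
        p = welch_t_pvalues(mat, log_transform=False)["g"]
        assert p == pytest.approx(0.287864, abs=1e-4)

    def test_label_swap_symmetry(self):
        mat = matrix_from_rows({"g": [1.0, 2.0, 3.0, 2.0, 3.0, 4.0]}, 3, 3)
        swapped = ExpressionMatrix(
            values=mat.values.copy(),
            groups=mat.groups.map({"control": "exposed", "exposed": "control"}),
        )
        assert welch_t_pvalues(swapped)["g"] == pytest.approx(
            welch_t_pvalues(mat)["g"], rel=1e-12
        )

    def test_requires_two_per_group(self):
        mat = matrix_from_rows({"g": [1.0, 2.0, 3.0, 4.0]}, 1, 3)
        with pytest.raises(ValidationError, match="2 samples"):
            welch_t_pvalues(mat)


class TestBhFdr:
    def test_stepup_worked_example(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_and_degenerate(self):
        assert bh_fdr([0.3]) == pytest.approx([0.3])
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.5])

    @given(
        p=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30),
        data=st.data(),
    )
    @settings(max_examples=200, derandomize=True)
    def test_adjustment_dominates_and_commutes_with_permutation(self, p, data):
        q = bh_fdr(p)
        assert np.all(q >= np.asarray(p) - 1e-12)
        assert np.all(q <= 1.0)
        perm = data.draw(st.permutations(range(len(p))))
        q_perm = bh_fdr([p[i] for i in perm])
        assert q_perm == pytest.approx([q[i] for i in perm])


class TestScreen:
    def test_threshold_definitions(self):
        df = pd.DataFrame(
            {
                "gene_id": ["a", "b", "c", "d"],
                "log2fc": [1.2, -0.9, -1.5, 1.0],
                "p": [0.01, 0.001, 0.2, 0.01],
            }
        )
        res = screen_degs(df)
        assert res.up == ("a", "d")  # log2fc exactly 1.0 is inclusive
        assert res.down == ()
        assert res.counts == {"total": 2, "up": 2, "down": 0}

    def test_up_down_partition(self):
        df = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(6)],
                "log2fc": [2.0, -2.0, 2.0, -2.0, 0.5, 1.5],
                "p": [0.01, 0.01, 0.5, 0.5, 0.01, 0.049],
            }
        )
        res = screen_degs(df)
        assert set(res.up).isdisjoint(res.down)
        assert res.counts["total"] == len(res.up) + len(res.down)

    def test_fdr_mode_never_finds_more_than_raw_mode(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(200)],
                "log2fc": rng.normal(0, 1.5, 200),
                "p": rng.uniform(0, 1, 200),
            }
        )
        raw = screen_degs(df, ScreenCriteria(use_adjusted=False))
        fdr = screen_degs(df, ScreenCriteria(use_adjusted=True))
        assert fdr.counts["total"] <= raw.counts["total"]

    def test_spiked_matrix_recovers_designed_counts(self):
        """7 up + 5 down spikes at |log2FC| = 2 in low noise: the screen
        returns exactly the designed counts."""
        mat, truth = gen_expression_matrix(SpikeDesign(seed=11))
        res = differential_expression(mat)
        assert res.counts == {"total": 12, "up": 7, "down": 5}
        spiked_up = set(truth.loc[truth.spike == "up", "gene_id"])
        spiked_down = set(truth.loc[truth.spike == "down", "gene_id"])
        assert set(res.up) == spiked_up
        assert set(res.down) == spiked_down


class TestDdct:
    @pytest.mark.parametrize(
        "ct, expected",
        [
            ((20.0, 18.0, 22.0, 20.0), 1.0),  # ddCt = 0
            ((21.0, 18.0, 22.0, 20.0), 0.5),  # ddCt = 1
            ((25.0, 20.0, 24.0, 20.0), 0.5),
            ((23.0, 20.0, 25.0, 20.0), 4.0),  # 2 cycles earlier = 4-fold up
        ],
    )
    def test_relative_expression(self, ct, expected):
        assert ddct_relative_expression(DdctInput(*ct)) == pytest.approx(expected)

    def test_nonfinite_ct_rejected(self):
        with pytest.raises(ValidationError, match="ct_target_treated"):
            DdctInput(float("nan"), 20.0, 24.0, 20.0)


class TestExpressionMatrixValidation:
    def test_duplicate_gene_ids_rejected(self):
        values = pd.DataFrame(
            [[1, 2], [3, 4]], index=["g", "g"], columns=["s1", "s2"]
        )
        groups = pd.Series({"s1": "control", "s2": "exposed"})
        with pytest.raises(ValidationError, match="duplicate"):
            ExpressionMatrix(values=values, groups=groups)

    def test_unlabelled_sample_rejected(self):
        values = pd.DataFrame([[1, 2]], index=["g"], columns=["s1", "s2"])
        with pytest.raises(ValidationError, match="s2"):
            ExpressionMatrix(values=values, groups=pd.Series({"s1": "control"}))

    def test_negative_values_rejected(self):
        values = pd.DataFrame([[1, -2]], index=["g"], columns=["s1", "s2"])
        groups = pd.Series({"s1": "control", "s2": "exposed"})
        with pytest.raises(ValidationError, match="non-negative"):
            ExpressionMatrix(values=values, groups=groups)
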