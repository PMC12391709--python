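import numpy as np
import pandas as pd
import pytest

from pahgtt.delphi import (
    Cutoffs,
    DelphiItemStats,
    ItemDecision,
    cutoffs,
    item_stats,
    kendall_w,
    panel_stats,
    select_items,
)


class TestItemStats:
    def test_unanimous_full_marks(self):
        stats = item_stats(np.full((6, 1), 5.0))
        assert stats[0].mj == 5.0 and stats[0].kj == 100.0 and stats[0].vj == 0.0

    def test_hand_computed_column(self):
        # scores 5, 4, 3: mean 4, one full mark of three experts, sample SD 1
        stats = item_stats(np.array([[5.0], [4.0], [3.0]]))
        assert stats[0].mj == 4.0
        assert stats[0].kj == pytest.approx(100.0 / 3)
        assert stats[0].vj == pytest.approx(0.25)

    def test_identical_columns_get_identical_stats(self):
        mat = np.array([[5, 5], [3, 3], [4, 4]], dtype=float)
        a, b = item_stats(mat)
        assert (a.mj, a.kj, a.vj) == (b.mj, b.kj, b.vj)

    def test_expert_order_invariance(self):
        rng = np.random.default_rng(0)
        mat = rng.integers(1, 6, size=(9, 5)).astype(float)
        shuffled = mat[rng.permutation(9)]
        for s1, s2 in zip(item_stats(mat), item_stats(shuffled)):
            assert s1.mj == pytest.approx(s2.mj) and s1.kj == pytest.approx(s2.kj)

    def test_out_of_scale_scores_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            item_stats(np.array([[6.0], [3.0]]))

    def test_dataframe_input_keeps_item_names(self):
        df = pd.DataFrame({"itemA": [5, 4], "itemB": [3, 3]})
        assert [s.item for s in item_stats(df)] == ["itemA", "itemB"]


class TestCutoffs:
    def test_hand_computed_four_item_fixture(self):
        stats = [
            DelphiItemStats("a", 4.0, 50.0, 0.10),
            DelphiItemStats("b", 3.0, 30.0, 0.20),
            DelphiItemStats("c", 5.0, 70.0, 0.30),
            DelphiItemStats("d", 4.0, 10.0, 0.40),
        ]
        cuts = cutoffs(stats)
        mj = np.array([4, 3, 5, 4.0])
        kj = np.array([50, 30, 70, 10.0])
        vj = np.array([0.1, 0.2, 0.3, 0.4])
        assert cuts.mj_cut == pytest.approx(mj.mean() - mj.std(ddof=1))
        assert cuts.kj_cut == pytest.approx(kj.mean() - kj.std(ddof=1))
        assert cuts.vj_cut == pytest.approx(vj.mean() + vj.std(ddof=1))

    def test_identical_items_all_retained_under_nonstrict_rule(self):
        stats = [DelphiItemStats(f"i{k}", 4.0, 40.0, 0.2) for k in range(5)]
        cuts = cutoffs(stats)
        decisions = select_items(stats, cuts)
        assert all(d == ItemDecision.retain for d in decisions.values())

    def test_synthetic_questionnaire_cuts_match_brute_force(self):
        # 19 experts scoring 31 candidate items on a 1-5 scale
        rng = np.random.default_rng(42)
        mat = np.clip(np.round(rng.normal(4.0, 0.8, size=(19, 31))), 1, 5)
        stats = item_stats(mat)
        cuts = cutoffs(stats)
        mj = np.array([c.mean() for c in mat.T])
        kj = np.array([100 * (c == 5).mean() for c in mat.T])
        vj = np.array([c.std(ddof=1) / c.mean() for c in mat.T])
        assert cuts.mj_cut == pytest.approx(mj.mean() - mj.std(ddof=1))
        assert cuts.kj_cut == pytest.approx(kj.mean() - kj.std(ddof=1))
        assert cuts.vj_cut == pytest.approx(vj.mean() + vj.std(ddof=1))

    def test_fewer_than_two_items_rejected(self):
        with pytest.raises(ValueError):
            cutoffs([DelphiItemStats("only", 4.0, 50.0, 0.1)])


class TestSelection:
    CUTS = Cutoffs(mj_cut=3.693, kj_cut=11.848, vj_cut=0.2)

    def test_three_criteria_rule(self):
        fail_all = DelphiItemStats("x", 3.0, 5.0, 0.5)
        pass_all = DelphiItemStats("y", 4.5, 60.0, 0.1)
        mixed = DelphiItemStats("z", 4.5, 5.0, 0.5)  # passes Mj only
        decisions = select_items([fail_all, pass_all, mixed], self.CUTS)
        assert decisions == {
            "x": ItemDecision.drop,
            "y": ItemDecision.retain,
            "z": ItemDecision.discuss,
        }

    def test_decisions_consistent_with_criteria_on_random_stats(self):
        rng = np.random.default_rng(1)
        stats = [
            DelphiItemStats(f"i{k}", rng.uniform(2, 5), rng.uniform(0, 80), rng.uniform(0.05, 0.5))
            for k in range(50)
        ]
        for item, decision in select_items(stats, self.CUTS).items():
            s = next(x for x in stats if x.item == item)
            n_pass = sum(
                [s.mj >= self.CUTS.mj_cut, s.kj >= self.CUTS.kj_cut, s.vj <= self.CUTS.vj_cut]
            )
            expected = (
                ItemDecision.retain if n_pass == 3
                else ItemDecision.drop if n_pass == 0
                else ItemDecision.discuss
            )
            assert decision == expected

    def test_undefined_vj_counts_as_failed_criterion(self):
        s = DelphiItemStats("u", 4.5, 60.0, None)
        assert select_items([s], self.CUTS)["u"] == ItemDecision.discuss


class TestKendallW:
    def test_identical_rankings_give_one(self):
        mat = np.tile(np.array([1.0, 2, 3, 4, 5]), (7, 1))
        assert kendall_w(mat) == pytest.approx(1.0)

    def test_two_experts_perfectly_reversed_give_zero(self):
        mat = np.array([[1.0, 2, 3], [3, 2, 1]])
        assert kendall_w(mat) == pytest.approx(0.0)

    def test_tie_correction_against_brute_force(self):
        rng = np.random.default_rng(3)
        mat = rng.integers(1, 6, size=(8, 6)).astype(float)
        from scipy.stats import rankdata

        m, n = mat.shape
        ranks = np.vstack([rankdata(r) for r in mat])
        s = ((ranks.sum(axis=0) - ranks.sum() / n) ** 2).sum()
        t = sum(
            float((c**3 - c).sum())
            for row in mat
            for c in [np.unique(row, return_counts=True)[1]]
        )
        expected = 12 * s / (m**2 * (n**3 - n) - m * t)
        assert kendall_w(mat) == pytest.approx(expected)

    def test_w_bounded_and_item_relabel_invariant(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            mat = rng.integers(1, 6, size=(5, 8)).astype(float)
            w = kendall_w(mat)
            assert 0.0 <= w <= 1.0
            perm = rng.permutation(8)
            assert kendall_w(mat[:, perm]) == pytest.approx(w)

    def test_random_scores_approach_null_distribution(self):
        # with many experts scoring at random, W concentrates near 0
        rng = np.random.default_rng(11)
        ws = [kendall_w(rng.integers(1, 6, size=(19, 24)).astype(float)) for _ in range(50)]
        assert np.mean(ws) < 0.15

    def test_single_item_rejected(self):
        with pytest.raises(ValueError):
            kendall_w(np.array([[1.0], [2.0]]))


class TestPanelStats:
    def test_full_response_rate(self):
        assert panel_stats(19, 19).positive_coefficient == 100.0

    def test_constant_authority_coefficients(self):
        out = panel_stats(10, 10, judgement_basis=[0.8] * 10, familiarity=[0.8] * 10)
        assert out.cr_mean == pytest.approx(0.80)
        assert out.cr_sd == pytest.approx(0.0)

    def test_tabulated_panel_fixture(self):
        ca = [0.9, 0.8, 0.7, 1.0]
        cs = [0.8, 0.9, 0.6, 0.7]
        cr = (np.array(ca) + np.array(cs)) / 2
        out = panel_stats(4, 4, judgement_basis=ca, familiarity=cs)
        assert out.cr_mean == pytest.approx(cr.mean())
        assert out.cr_sd == pytest.approx(cr.std(ddof=1))

    def test_missing_authority_inputs_omitted(self):
        out = panel_stats(19, 18)
        assert out.cr_mean is None and out.cr_sd is None
        assert out.positive_coefficient == pytest.approx(94.74)

    def test_invalid_coefficients_rejected(self):
        with pytest.raises(ValueError):
            panel_stats(5, 5, judgement_basis=[1.2] * 5, familiarity=[0.5] * 5)
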