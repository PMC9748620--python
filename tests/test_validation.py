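"""Classification measures, venetian-blinds CV, Monte-Carlo validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import xrfpit as xp
from xrfpit.validation import confusion_metrics, venetian_folds


def _label_vectors(n_non, correct_non, n_bp, correct_bp):
    true = ["non_BP"] * n_non + ["BP"] * n_bp
    pred = (
        ["non_BP"] * correct_non + ["BP"] * (n_non - correct_non)
        + ["BP"] * correct_bp + ["non_BP"] * (n_bp - correct_bp)
    )
    return true, pred


class TestConfusionMetrics:
    def test_printed_training_row_reconstruction(self):
        # Sn 0.77 and Sp 0.79 imply BA 0.78
        m = confusion_metrics(*_label_vectors(100, 77, 100, 79))
        assert (m.sensitivity, m.specificity, m.balanced_accuracy) == (0.77, 0.79, 0.78)

    def test_perfect_predictions(self):
        m = confusion_metrics(*_label_vectors(5, 5, 5, 5))
        assert (m.sensitivity, m.specificity, m.balanced_accuracy) == (1.0, 1.0, 1.0)

    def test_hand_counted_confusion_table(self):
        m = confusion_metrics(*_label_vectors(10, 8, 10, 6))
        assert m.sensitivity == pytest.approx(0.8)
        assert m.specificity == pytest.approx(0.6)
        assert m.balanced_accuracy == pytest.approx(0.7)
        assert m.confusion.sum() == 20

    def test_absent_class_named_in_error(self):
        with pytest.raises(ValueError, match="BP"):
            confusion_metrics(["non_BP", "non_BP"], ["non_BP", "BP"])

    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=4).filter(
        lambda lp: any(t for t, _ in lp) and any(not t for t, _ in lp)
    ))
    def test_swapping_class_roles_swaps_sn_sp_keeps_ba(self, pairs):
        names = np.array(["non_BP", "BP"])
        true = names[[int(t) for t, _ in pairs]]
        pred = names[[int(p) for _, p in pairs]]
        m = confusion_metrics(true, pred)
        swap = {"BP": "non_BP", "non_BP": "BP"}
        m_sw = confusion_metrics([swap[t] for t in true], [swap[p] for p in pred])
        assert m_sw.sensitivity == pytest.approx(m.specificity)
        assert m_sw.specificity == pytest.approx(m.sensitivity)
        assert m_sw.balanced_accuracy == pytest.approx(m.balanced_accuracy)


class TestVenetianFolds:
    @pytest.mark.parametrize(
        "n,k,expect",
        [
            (10, 5, [0, 1, 2, 3, 4, 0, 1, 2, 3, 4]),
            (7, 5, [0, 1, 2, 3, 4, 0, 1]),
            (5, 5, [0, 1, 2, 3, 4]),
        ],
    )
    def test_fold_rule_is_i_mod_k(self, n, k, expect):
        assert venetian_folds(n, k).tolist() == expect

    def test_fold_sizes_differ_by_at_most_one(self):
        sizes = np.bincount(venetian_folds(7, 5), minlength=5)
        assert sizes.tolist() == [2, 2, 1, 1, 1]

    def test_n_below_k_rejected(self):
        with pytest.raises(ValueError):
            venetian_folds(4, 5)

    @given(st.integers(2, 20), st.integers(2, 20))
    def test_pure_function_of_n_and_k(self, n, k):
        if n < k:
            return
        a, b = venetian_folds(n, k), venetian_folds(n, k)
        assert np.array_equal(a, b)
        assert np.array_equal(a, np.arange(n) % k)


class TestCrossValidation:
    def test_separable_classes_reach_perfect_ba(self, default_cfg):
        cfg = default_cfg.replace(
            bp_effects={"K": 3.0, "Ca": 0.2},
            between_fruit_cv=0.02,
            within_fruit_cv=0.02,
            points_per_fruit=1,
        )
        sset = xp.generate_balanced_study(cfg, 30, seed=0)
        m = xp.cross_validate_plsda(sset, 5, 2)
        assert m.balanced_accuracy == 1.0

    def test_permuted_labels_give_chance_level(self, default_cfg):
        cfg = default_cfg.replace(points_per_fruit=1)
        sset = xp.generate_balanced_study(cfg, 176, seed=21)
        rng = np.random.default_rng(77)
        sset.meta["label"] = rng.permutation(sset.meta["label"].to_numpy())
        sset.meta["severity"] = np.where(sset.meta["label"] == "non_BP", "none", "moderate")
        m = xp.cross_validate_plsda(sset, 5, 4)
        assert 0.42 <= m.balanced_accuracy <= 0.58

    def test_deterministic_across_runs(self, small_balanced):
        a = xp.cross_validate_plsda(small_balanced, 5, 3)
        b = xp.cross_validate_plsda(small_balanced, 5, 3)
        assert a.balanced_accuracy == b.balanced_accuracy
        assert np.array_equal(a.confusion, b.confusion)

    def test_pooled_confusion_counts_all_samples(self, small_balanced):
        m = xp.cross_validate_plsda(small_balanced, 5, 3)
        assert m.confusion.sum() == small_balanced.n_spectra

    def test_points_of_one_fruit_share_folds(self, small_balanced):
        # grouped splitting: an injected extreme value in one point must not
        # leak into any training fold containing that fruit's other points —
        # verified structurally through the fruit-level fold table
        from xrfpit.validation import _fruit_table

        fruit = _fruit_table(small_balanced, True)
        folds = venetian_folds(len(fruit), 5)
        fold_of = dict(zip(fruit["fruit_id"], folds))
        per_spec = small_balanced.meta["fruit_id"].map(fold_of)
        assert per_spec.groupby(small_balanced.meta["fruit_id"]).nunique().eq(1).all()


class TestMonteCarlo:
    def test_single_iteration_reduces_to_one_holdout(self, small_balanced):
        m = xp.monte_carlo_validate(small_balanced, n_iter=1, n_lv=3, seed=5)
        assert len(m.per_iteration) == 1
        row = m.per_iteration.iloc[0]
        assert m.balanced_accuracy == row["BA"]
        assert m.sensitivity == row["Sn"]

    def test_agrees_with_venetian_cv(self, default_cfg):
        sset = xp.generate_balanced_study(default_cfg, 100, seed=31)
        cv = xp.cross_validate_plsda(sset, 5, 4)
        mc = xp.monte_carlo_validate(sset, n_iter=100, n_lv=4, seed=31)
        assert abs(mc.balanced_accuracy - cv.balanced_accuracy) <= 0.03

    def test_stable_across_seeds_at_100_iterations(self, default_cfg):
        cfg = default_cfg.replace(points_per_fruit=2)
        sset = xp.generate_balanced_study(cfg, 60, seed=41)
        a = xp.monte_carlo_validate(sset, n_iter=100, n_lv=4, seed=1)
        b = xp.monte_carlo_validate(sset, n_iter=100, n_lv=4, seed=2)
        assert abs(a.balanced_accuracy - b.balanced_accuracy) <= 0.02

    def test_ba_is_mean_of_sn_sp_per_iteration(self, small_balanced):
        m = xp.monte_carlo_validate(small_balanced, n_iter=5, n_lv=3, seed=9)
        per = m.per_iteration
        np.testing.assert_allclose(per["BA"], (per["Sn"] + per["Sp"]) / 2)


class TestIncidence:
    def test_orchard_table_percentages(self):
        rows = []
        for cult, total, bp in [("GS", 5267, 971), ("BF", 4375, 159), ("FJ", 2899, 71)]:
            for i in range(total):
                lab = "BP" if i < bp else "non_BP"
                rows.append((f"{cult}-{i}", cult, 1, lab, "moderate" if lab == "BP" else "none"))
        meta = pd.DataFrame(rows, columns=["fruit_id", "cultivar", "point", "label", "severity"])
        pct = xp.incidence(meta)
        assert pct["GS"] == 18.4
        assert pct["BF"] == 3.6
        assert pct["FJ"] == 2.4

    def test_zero_incidence(self):
        meta = pd.DataFrame(
            {
                "fruit_id": [f"f{i}" for i in range(100)],
                "cultivar": "GS",
                "point": 1,
                "label": "non_BP",
                "severity": "none",
            }
        )
        assert xp.incidence(meta)["GS"] == 0.0

    def test_empty_meta_rejected(self):
        with pytest.raises(ValueError):
            xp.incidence(pd.DataFrame(columns=["fruit_id", "cultivar", "label"]))
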