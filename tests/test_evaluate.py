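from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sixma.evaluate import (
    ConfusionCounts,
    auc,
    confusion,
    independent_eval,
    jackknife_cv,
    kfold_cv,
    mcc_from_counts,
    mcc_ratio_form,
    metrics,
    ratio_split_eval,
    roc_auc,
    roc_curve,
)
from sixma.model import RFConfig, train


def mann_whitney_oracle(y, scores) -> Fraction:
    """Exhaustive pairwise rank count: P(pos > neg) + 1/2 P(tie)."""
    pos = [s for t, s in zip(y, scores) if t == 1]
    neg = [s for t, s in zip(y, scores) if t == 0]
    total = Fraction(0)
    for p in pos:
        for n in neg:
            if p > n:
                total += 1
            elif p == n:
                total += Fraction(1, 2)
    return total / (len(pos) * len(neg))


confusion_tables = st.tuples(
    st.integers(1, 200), st.integers(1, 200), st.floats(0, 1), st.floats(0, 1)
).map(lambda t: ConfusionCounts(t[0], t[1], int(t[2] * t[0]), int(t[3] * t[1])))


class TestConfusion:
    def test_perfect_agreement(self):
        c = confusion([1, 1, 0, 0], [1, 1, 0, 0])
        assert (c.fn, c.fp) == (0, 0)

    def test_total_disagreement(self):
        c = confusion([1, 1, 0, 0], [0, 0, 1, 1])
        assert (c.fn, c.fp) == (c.n_pos, c.n_neg)

    def test_hand_count(self):
        c = confusion([1, 1, 0, 0], [1, 0, 1, 0])
        assert (c.n_pos, c.n_neg, c.fn, c.fp) == (2, 2, 1, 1)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            confusion([1, 0], [1])

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            confusion([1, 2], [1, 0])

    def test_count_bounds_enforced(self):
        with pytest.raises(ValueError):
            ConfusionCounts(n_pos=2, n_neg=2, fn=3, fp=0)


class TestMetrics:
    def test_all_correct_mcc_one(self):
        rep = metrics(ConfusionCounts(50, 50, 0, 0))
        assert rep.mcc == 1.0
        assert (rep.sn, rep.sp, rep.acc) == (1.0, 1.0, 1.0)

    def test_half_wrong_mcc_zero(self):
        rep = metrics(ConfusionCounts(100, 100, 50, 50))
        assert rep.mcc == 0.0

    def test_all_wrong_mcc_minus_one(self):
        rep = metrics(ConfusionCounts(40, 60, 40, 60))
        assert rep.mcc == -1.0
        assert (rep.sn, rep.sp, rep.acc) == (0.0, 0.0, 0.0)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            metrics(ConfusionCounts(0, 10, 0, 2))

    def test_zero_marginal_warns_and_zeroes(self):
        # every sample predicted positive -> a zero column marginal
        with pytest.warns(UserWarning, match="zero marginal"):
            rep = metrics(ConfusionCounts(5, 5, 0, 5))
        assert rep.mcc == 0.0

    @given(confusion_tables)
    @settings(max_examples=300, deadline=None)
    def test_metric_identities(self, c):
        rep = metrics(c)
        assert 0 <= rep.sn <= 1 and 0 <= rep.sp <= 1 and 0 <= rep.acc <= 1
        assert rep.acc == pytest.approx(
            (rep.sn * c.n_pos + rep.sp * c.n_neg) / (c.n_pos + c.n_neg)
        )
        assert -1 <= rep.mcc <= 1

    @given(confusion_tables)
    @settings(max_examples=300, deadline=None)
    def test_ratio_form_equals_standard_form(self, c):
        tp, tn = c.tp, c.tn
        if min(tp + c.fp, tp + c.fn, tn + c.fp, tn + c.fn) == 0:
            return  # both forms degenerate; covered elsewhere
        assert abs(mcc_ratio_form(c) - mcc_from_counts(c)) <= 1e-12


class TestRoc:
    def test_perfect_separation_passes_through_0_1(self):
        pts = roc_curve([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert [0.0, 1.0] in pts.tolist()
        assert auc(pts) == 1.0

    def test_constant_scores_collapse(self):
        pts = roc_curve([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert pts[0].tolist() == [0.0, 0.0]
        assert pts[-1].tolist() == [1.0, 1.0]
        assert auc(pts) == pytest.approx(0.5)

    def test_fpr_tpr_non_decreasing(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 50)
        y[:2] = [0, 1]
        s = rng.random(50).round(1)  # force ties
        pts = roc_curve(y, s)
        assert (np.diff(pts[:, 0]) >= 0).all()
        assert (np.diff(pts[:, 1]) >= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_curve([1, 1], [0.2, 0.8])

    def test_score_negation_antisymmetry(self):
        rng = np.random.default_rng(4)
        y = np.r_[np.zeros(20), np.ones(20)].astype(int)
        s = rng.random(40)
        assert auc(roc_curve(y, -s)) == pytest.approx(1 - auc(roc_curve(y, s)))

    def test_auc_needs_two_points(self):
        with pytest.raises(ValueError):
            auc(np.array([[0.0, 0.0]]))

    def test_matches_pairwise_rank_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = rng.integers(4, 31)
            y = rng.integers(0, 2, n)
            y[:2] = [0, 1]
            s = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)  # force ties
            expected = float(mann_whitney_oracle(y, s))
            assert auc(roc_curve(y, s)) == pytest.approx(expected, abs=1e-12)

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(12)
        n = 4000
        y = rng.integers(0, 2, n)
        s = rng.random(n)  # independent of labels
        # null sd of AUC (Mann-Whitney) ~ sqrt((n1+n2+1)/(12 n1 n2))
        n1, n2 = (y == 1).sum(), (y == 0).sum()
        sd = np.sqrt((n1 + n2 + 1) / (12 * n1 * n2))
        assert abs(auc(roc_curve(y, s)) - 0.5) < 3 * sd


class FirstFeatureClassifier:
    """Trivial seam replacement: score = min-max scaled first feature."""

    def __init__(self, X):
        col = np.asarray(X)[:, 0]
        self.lo, self.hi = float(col.min()), float(col.max())

    def scores(self, X):
        col = np.asarray(X)[:, 0].astype(float)
        if self.hi == self.lo:
            return np.full(len(col), 0.5)
        return np.clip((col - self.lo) / (self.hi - self.lo), 0, 1)


def first_feature_trainer(X, y):
    return FirstFeatureClassifier(X)


FAST_RF = RFConfig(n_trees=15)


class TestKfoldCv:
    def test_every_sample_scored_once(self, small_biased_fixture):
        # the internal assertion fires if the partition property fails
        rep = kfold_cv(small_biased_fixture, schemes="nv", config=FAST_RF, k=5, seed=2)
        assert rep.counts.n_pos == rep.counts.n_neg == 100

    def test_separable_fixture_auc(self, small_biased_fixture):
        rep = kfold_cv(small_biased_fixture, schemes="mnbe", config=FAST_RF, k=5, seed=2)
        assert rep.auc >= 0.9

    def test_protocol_metadata(self, small_biased_fixture):
        rep = kfold_cv(small_biased_fixture, schemes="mnbe", config=FAST_RF, k=5, seed=2)
        assert rep.protocol["name"] == "kfold_cv"
        assert rep.protocol["k"] == 5
        assert rep.protocol["seed"] == 2
        assert rep.protocol["rf_seed"] == FAST_RF.seed

    def test_k_too_small(self, small_biased_fixture):
        with pytest.raises(ValueError, match="k must be"):
            kfold_cv(small_biased_fixture, k=1)

    def test_class_too_small_for_stratification(self, small_biased_fixture):
        few = [w for w in small_biased_fixture if w.label == 1][:3] + [
            w for w in small_biased_fixture if w.label == 0
        ][:20]
        with pytest.raises(ValueError, match="fewer than k"):
            kfold_cv(few, schemes="nv", k=5)

    def test_seam_accepts_custom_trainer(self, small_biased_fixture):
        rep = kfold_cv(
            small_biased_fixture, schemes="nv", k=5, seed=2,
            trainer=first_feature_trainer,
        )
        assert rep.auc is not None  # ran end-to-end without an RF

    def test_determinism(self, small_biased_fixture):
        a = kfold_cv(small_biased_fixture, schemes="nv", config=FAST_RF, k=5, seed=2)
        b = kfold_cv(small_biased_fixture, schemes="nv", config=FAST_RF, k=5, seed=2)
        assert a.auc == b.auc and a.acc == b.acc


class TestRatioSplit:
    def test_partition_and_determinism(self, small_biased_fixture):
        t1, tr1 = ratio_split_eval(
            small_biased_fixture, schemes="mnbe", config=FAST_RF,
            train_fraction=0.7, seed=5,
        )
        t2, _ = ratio_split_eval(
            small_biased_fixture, schemes="mnbe", config=FAST_RF,
            train_fraction=0.7, seed=5,
        )
        assert t1.auc == t2.auc
        total = t1.counts.n_pos + t1.counts.n_neg + tr1.counts.n_pos + tr1.counts.n_neg
        assert total == len(small_biased_fixture)

    def test_both_parts_reported(self, small_biased_fixture):
        testing, training = ratio_split_eval(
            small_biased_fixture, schemes="mnbe", config=FAST_RF,
            train_fraction=0.5, seed=5,
        )
        assert testing.protocol["part"] == "testing"
        assert training.protocol["part"] == "training"
        assert training.protocol["inner_k"] == 5

    def test_invalid_fraction(self, small_biased_fixture):
        with pytest.raises(ValueError, match="train_fraction"):
            ratio_split_eval(small_biased_fixture, train_fraction=1.0)

    def test_testing_auc_trends_up_with_training_size(self, biased_fixture):
        # trend over seeds, not per-seed: average testing AUC at 90/10
        # should not fall below the 50/50 average
        subset = biased_fixture[:300] + biased_fixture[1000:1300]
        lo, hi = [], []
        for seed in (1, 2, 3):
            t_lo, _ = ratio_split_eval(
                subset, schemes="nv", config=FAST_RF,
                train_fraction=0.5, seed=seed,
            )
            t_hi, _ = ratio_split_eval(
                subset, schemes="nv", config=FAST_RF,
                train_fraction=0.9, seed=seed,
            )
            lo.append(t_lo.auc)
            hi.append(t_hi.auc)
        assert np.mean(hi) >= np.mean(lo) - 0.05


class TestJackknife:
    def test_toy_set_each_scored_once(self, small_biased_fixture):
        toy = small_biased_fixture[:5] + small_biased_fixture[100:105]
        rep = jackknife_cv(toy, schemes="nv", trainer=first_feature_trainer)
        assert rep.counts.n_pos + rep.counts.n_neg == 10
        assert rep.protocol["name"] == "jackknife"

    def test_separable_fixture_accuracy(self, small_biased_fixture):
        rep = jackknife_cv(small_biased_fixture, schemes="mnbe", config=FAST_RF)
        assert rep.acc >= 0.9

    def test_cap_enforced(self, small_biased_fixture):
        with pytest.raises(ValueError, match="cap"):
            jackknife_cv(small_biased_fixture, schemes="nv", cap=10)

    def test_equals_n_fold_cv(self, small_biased_fixture):
        toy = small_biased_fixture[:6] + small_biased_fixture[100:106]
        jk = jackknife_cv(toy, schemes="nv", trainer=first_feature_trainer)
        kf = kfold_cv(toy, schemes="nv", k=len(toy), seed=0,
                      trainer=first_feature_trainer)
        assert jk.auc == pytest.approx(kf.auc)
        assert jk.acc == pytest.approx(kf.acc)


@pytest.fixture(scope="module")
def fitted(small_biased_fixture):
    from sixma.encoders import encode_matrix

    df = encode_matrix(small_biased_fixture, ["mnbe"], with_labels=True)
    y = df.pop("label").to_numpy()
    return train(df, y, FAST_RF, metadata={"schemes": "mnbe"})


class TestIndependentEval:
    def test_training_set_sanity(self, small_biased_fixture, fitted):
        rep = independent_eval(fitted, small_biased_fixture)
        assert rep.acc == 1.0

    def test_held_out_from_same_generator(self, fitted):
        from sixma.synthetic import SyntheticSpec, generate

        held = generate(SyntheticSpec(n_pos=100, n_neg=100, bias_strength=1.0, seed=99))
        rep = independent_eval(fitted, held)
        assert rep.auc >= 0.9

    def test_composition_identity(self, small_biased_fixture, fitted):
        from sixma.encoders import encode_matrix
        from sixma.model import predict_scores

        rep = independent_eval(fitted, small_biased_fixture, threshold=0.5)
        df = encode_matrix(small_biased_fixture, ["mnbe"], with_labels=True)
        y = df.pop("label").to_numpy()
        manual = metrics(confusion(y, (predict_scores(fitted, df) >= 0.5).astype(int)))
        assert (rep.sn, rep.sp, rep.acc, rep.mcc) == (
            manual.sn, manual.sp, manual.acc, manual.mcc,
        )

    def test_single_class_test_set(self, small_biased_fixture, fitted):
        pos_only = [w for w in small_biased_fixture if w.label == 1][:20]
        rep = independent_eval(fitted, pos_only)
        assert rep.auc is None and rep.roc is None
        assert rep.sn == 1.0  # separable fit scores its positives correctly
        assert np.isnan(rep.sp)

    def test_to_dict_serialisable(self, small_biased_fixture, fitted):
        import json

        rep = independent_eval(fitted, small_biased_fixture)
        assert json.loads(json.dumps(rep.to_dict()))["counts"]["n_pos"] == 100
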