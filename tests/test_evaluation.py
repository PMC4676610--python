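"""Metrics algebra, balanced bootstraps, the subject sweep, and embedding."""

import numpy as np
import pytest
from scipy.linalg import subspace_angles
from sklearn.metrics import precision_score, recall_score

import gaitguard as gg
from gaitguard.evaluation import (
    balanced_bootstrap,
    classification_metrics,
    cross_subject_sweep,
    embed_2d,
)
from gaitguard.features import LabeledFrameSet
from gaitguard.protocol import ExperimentHistory


def labels(*pairs):
    """Build (predicted, true) arrays from (true, predicted, count) triples."""
    t, p = [], []
    for true, pred, k in pairs:
        t += [true] * k
        p += [pred] * k
    return np.array(p, dtype=object), np.array(t, dtype=object)


def toy_frameset(n, label, subject, seed=0, d=6):
    rng = np.random.default_rng(seed)
    return LabeledFrameSet(
        X=rng.normal(size=(n, d)),
        y=np.full(n, label, dtype=object),
        honesty=np.full(n, "normal", dtype=object),
        subject_id=np.full(n, subject, dtype=object),
        trial_id=np.full(n, "0", dtype=object),
        frame_start=np.arange(n),
    )


class TestMetrics:
    def test_hand_computed_confusion(self):
        # true walking: 8 detected, 2 missed; true sitting: 6 detected, 4 missed
        pred, true = labels(
            ("walking", "walking", 8),
            ("walking", "sitting", 2),
            ("sitting", "sitting", 6),
            ("sitting", "walking", 4),
        )
        m = classification_metrics(pred, true)
        assert m.accuracy == pytest.approx(0.70)
        assert m.recall["walking"] == pytest.approx(0.80)
        assert m.precision["walking"] == pytest.approx(8 / 12)
        assert m.sensitivity == pytest.approx(0.80)
        assert m.specificity == pytest.approx(0.60)
        assert m.confusion.sum() == m.n == 20
        # independent cross-check against sklearn
        assert m.precision["walking"] == pytest.approx(
            precision_score(true, pred, pos_label="walking")
        )
        assert m.recall["sitting"] == pytest.approx(
            recall_score(true, pred, pos_label="sitting")
        )
        # accuracy equals the class-weighted mean of recalls
        weights = m.confusion.sum(axis=1) / m.n
        assert m.accuracy == pytest.approx(
            weights[0] * m.recall["sitting"] + weights[1] * m.recall["walking"]
        )

    def test_perfect_and_single_wrong(self):
        pred, true = labels(("walking", "walking", 5), ("sitting", "sitting", 5))
        m = classification_metrics(pred, true)
        assert m.accuracy == 1.0 and m.recall["walking"] == 1.0
        m1 = classification_metrics(["walking"], ["sitting"])
        assert m1.accuracy == 0.0

    def test_undefined_ratios_are_nan(self):
        m = classification_metrics(["sitting", "sitting"], ["sitting", "sitting"])
        assert np.isnan(m.precision["walking"])  # no walking predictions
        assert np.isnan(m.sensitivity)  # no walking truths
        assert m.accuracy == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            classification_metrics(["sitting"], ["sitting", "walking"])


class TestBalancedBootstrap:
    def test_size_and_pool_membership(self):
        normal = toy_frameset(50, "sitting", "A", 1)
        out = balanced_bootstrap(normal, None, 30, 2)
        assert len(out) == 30
        norm_rows = {r.tobytes() for r in normal.X}
        assert all(r.tobytes() in norm_rows for r in out.X)

    def test_pooled_with_deceptive(self):
        normal = toy_frameset(20, "sitting", "A", 3)
        deceptive = toy_frameset(20, "walking", "A", 4)
        out = balanced_bootstrap(normal, deceptive, 200, 5)
        pool = {r.tobytes() for r in normal.X} | {r.tobytes() for r in deceptive.X}
        assert len(out) == 200
        assert all(r.tobytes() in pool for r in out.X)
        # with replacement from both halves: both represented at this size
        assert {"sitting", "walking"} == set(out.y)

    def test_deterministic(self):
        normal = toy_frameset(40, "sitting", "A", 6)
        a = balanced_bootstrap(normal, None, 25, 7)
        b = balanced_bootstrap(normal, None, 25, 7)
        assert np.array_equal(a.X, b.X)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            balanced_bootstrap(LabeledFrameSet.empty(6), None, 10, 0)
        with pytest.raises(ValueError):
            balanced_bootstrap(toy_frameset(5, "sitting", "A"), None, 0, 0)


def two_class_history(subject, seed):
    rng = np.random.default_rng(seed)
    normal = LabeledFrameSet(
        X=np.vstack([rng.normal(0, 1, (20, 6)), rng.normal(4, 1, (20, 6))]),
        y=np.array(["sitting"] * 20 + ["walking"] * 20, dtype=object),
        honesty=np.full(40, "normal", dtype=object),
        subject_id=np.full(40, subject, dtype=object),
        trial_id=np.full(40, "n", dtype=object),
        frame_start=np.arange(40),
    )
    deceptive = LabeledFrameSet(
        X=rng.normal(8, 1, (20, 6)),
        y=np.array(["sitting"] * 20, dtype=object),
        honesty=np.full(20, "deceptive", dtype=object),
        subject_id=np.full(20, subject, dtype=object),
        trial_id=np.full(20, "d", dtype=object),
        frame_start=np.arange(20),
    )
    return ExperimentHistory(
        subject_id=subject,
        rounds=[],
        terminal_reason="max_rounds",
        normal_data=normal,
        deceptive_data=deceptive,
        final_forest=None,
    )


class TestSweep:
    def test_two_subject_cohort_is_losi_and_loso(self):
        hist = [two_class_history("A", 0), two_class_history("B", 1)]
        rep = cross_subject_sweep(
            hist,
            repeats=2,
            rng=0,
            forest_config=gg.ForestConfig(n_trees=3, n_split_candidates=2),
        )
        df = rep.to_frame()
        assert set(df.n_train) == {1}
        assert len(df) == 2 * 2 * 2  # repeats x condition x honesty
        # LOSO at cohort of 2: repeats enumerate the held-out subject
        held = set(df[df.repeat == 0].test_subjects) | set(df[df.repeat == 1].test_subjects)
        assert held == {"A", "B"}
        # partitions disjoint and shared between baseline and expert
        for (_, _, hon), grp in df.groupby(["n_train", "repeat", "honesty"]):
            assert len(set(grp.train_subjects)) == 1
            for tr, te in zip(grp.train_subjects, grp.test_subjects):
                assert not set(tr.split("|")) & set(te.split("|"))

    def test_oracle_trainer_gets_perfect_accuracy(self):
        hist = [two_class_history(s, i) for i, s in enumerate("ABCD")]
        truth = {}
        for h in hist:
            for fs in (h.normal_data, h.deceptive_data):
                for row, lab in zip(fs.X, fs.y):
                    truth[row.tobytes()] = lab

        class Oracle:
            def predict(self, X):
                return np.array([truth[r.tobytes()] for r in X], dtype=object)

        rep = cross_subject_sweep(hist, repeats=2, rng=1, trainer=lambda d, s: Oracle())
        assert (rep.to_frame().accuracy == 1.0).all()

    def test_deterministic_given_seed(self):
        hist = [two_class_history(s, i) for i, s in enumerate("ABC")]
        a = cross_subject_sweep(hist, repeats=2, rng=5, forest_config=gg.ForestConfig(n_trees=3, n_split_candidates=2))
        b = cross_subject_sweep(hist, repeats=2, rng=5, forest_config=gg.ForestConfig(n_trees=3, n_split_candidates=2))
        assert a.to_frame().equals(b.to_frame())

    def test_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            cross_subject_sweep([two_class_history("A", 0)], repeats=1)


class TestEmbed2d:
    def test_dimension_contract_and_duplicates(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 8))
        X[1] = X[0]
        E = embed_2d(X)
        assert E.shape == (30, 2)
        assert np.allclose(E[0], E[1])

    def test_recovers_planted_two_factor_subspace(self):
        rng = np.random.default_rng(1)
        Z = rng.normal(size=(400, 2))
        L = rng.normal(size=(12, 2))
        X = Z @ L.T + 0.05 * rng.normal(size=(400, 12))
        E = embed_2d(X)
        angles = subspace_angles(E, Z)
        assert np.degrees(angles).max() < 10.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            embed_2d(np.zeros((10, 5)))
        with pytest.raises(ValueError):
            embed_2d(np.random.default_rng(2).normal(size=(2, 5)))
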