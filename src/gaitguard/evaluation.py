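"""Cross-subject baseline-vs-expert evaluation and the 2-factor embedding.

The *baseline* classifier is trained only on normal activity frames; the
*expert* classifier additionally sees deceptive frames labeled with the true
activity. To keep the comparison fair both are trained on bootstrap samples
of identical size. The sweep varies the number of training subjects from 1
(leave-one-subject-in) to cohort - 1 (leave-one-subject-out) and evaluates
both classifiers on held-out subjects' deceptive and normal frames
separately; accuracy always means detecting the *true* activity, so a frame
of seated phone-shaking counts as correct only when predicted "sitting".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import FactorAnalysis

from .features import LabeledFrameSet
from .forest import ForestConfig, train_forest
from .protocol import ExperimentHistory
from .simulate import SITTING, WALKING, as_rng

CLASSES = (SITTING, WALKING)
POSITIVE_CLASS = WALKING  # convention for sensitivity/specificity


@dataclass
class Metrics:
    """Confusion-matrix summary; undefined ratios are NaN, never 0."""

    accuracy: float
    sensitivity: float  # recall of the positive class (walking)
    specificity: float  # recall of the negative class (sitting)
    precision: dict
    recall: dict
    confusion: np.ndarray  # rows true, cols predicted, class order CLASSES
    n: int


def classification_metrics(predicted, true) -> Metrics:
    """Accuracy, per-class precision/recall, sensitivity/specificity."""
    predicted = np.asarray(predicted, dtype=object)
    true = np.asarray(true, dtype=object)
    if predicted.shape != true.shape or predicted.size == 0:
        raise ValueError("predicted and true labels must be equal-length, non-empty")
    conf = np.zeros((2, 2), dtype=int)
    for i, c_true in enumerate(CLASSES):
        for j, c_pred in enumerate(CLASSES):
            conf[i, j] = int(np.sum((true == c_true) & (predicted == c_pred)))

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    recall = {c: ratio(conf[i, i], conf[i, :].sum()) for i, c in enumerate(CLASSES)}
    precision = {c: ratio(conf[i, i], conf[:, i].sum()) for i, c in enumerate(CLASSES)}
    pos = CLASSES.index(POSITIVE_CLASS)
    return Metrics(
        accuracy=ratio(int(np.trace(conf)), int(conf.sum())),
        sensitivity=recall[CLASSES[pos]],
        specificity=recall[CLASSES[1 - pos]],
        precision=precision,
        recall=recall,
        confusion=conf,
        n=int(conf.sum()),
    )


def balanced_bootstrap(
    normal: LabeledFrameSet,
    deceptive: LabeledFrameSet | None,
    target_size: int,
    rng: np.random.Generator | int | None = None,
) -> LabeledFrameSet:
    """Uniform with-replacement sample of ``target_size`` rows.

    Pool is the normal frames alone (baseline) or normal plus deceptive
    frames (expert); equal ``target_size`` makes the two training sets the
    same size.
    """
    if target_size < 1:
        raise ValueError("target_size must be >= 1")
    pool = normal if deceptive is None or len(deceptive) == 0 else LabeledFrameSet.concat(
        [normal, deceptive]
    )
    if len(pool) == 0:
        raise ValueError("empty sampling pool")
    rng = as_rng(rng)
    idx = rng.integers(0, len(pool), target_size)
    return pool.subset(idx)


@dataclass
class SweepCell:
    n_train: int
    repeat: int
    condition: str  # "baseline" | "expert"
    honesty: str  # test-set honesty: "normal" | "deceptive"
    metrics: Metrics
    train_subjects: tuple
    test_subjects: tuple


@dataclass
class EvaluationReport:
    """All cells of the training-subject sweep, with tidy-frame export."""

    cells: list[SweepCell] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            rows.append(
                {
                    "n_train": c.n_train,
                    "repeat": c.repeat,
                    "condition": c.condition,
                    "honesty": c.honesty,
                    "accuracy": c.metrics.accuracy,
                    "sensitivity": c.metrics.sensitivity,
                    "specificity": c.metrics.specificity,
                    "precision_sitting": c.metrics.precision[SITTING],
                    "precision_walking": c.metrics.precision[WALKING],
                    "recall_sitting": c.metrics.recall[SITTING],
                    "recall_walking": c.metrics.recall[WALKING],
                    "n_test": c.metrics.n,
                    "train_subjects": "|".join(c.train_subjects),
                    "test_subjects": "|".join(c.test_subjects),
                }
            )
        return pd.DataFrame(rows)

    def mean_accuracy(self, condition: str, honesty: str) -> dict[int, float]:
        """Mean accuracy per n_train for one condition/test-honesty pair."""
        df = self.to_frame()
        sel = df[(df.condition == condition) & (df.honesty == honesty)]
        return sel.groupby("n_train")["accuracy"].mean().to_dict()


def _default_factory(config: ForestConfig, seed: int):
    def train(data: LabeledFrameSet):
        cfg = ForestConfig(
            n_trees=config.n_trees,
            n_split_candidates=config.n_split_candidates,
            split_criterion=config.split_criterion,
            min_leaf=config.min_leaf,
            max_depth=config.max_depth,
            seed=seed,
            bootstrap=config.bootstrap,
        )
        return train_forest(data, cfg)

    return train


def cross_subject_sweep(
    histories: list[ExperimentHistory],
    repeats: int = 10,
    forest_config: ForestConfig | None = None,
    rng: np.random.Generator | int | None = None,
    n_train_values: list[int] | None = None,
    trainer=None,
) -> EvaluationReport:
    """Baseline-vs-expert sweep over the number of training subjects.

    ``n_train = 1`` is the leave-one-subject-in setting; ``n_train =
    cohort - 1`` is leave-one-subject-out, where repeats enumerate the
    held-out subject instead of resampling the partition. ``trainer`` may
    replace the forest trainer (e.g. with an oracle) for plumbing tests: it
    is called as ``trainer(data, seed)`` and must return an object with a
    ``predict`` method.
    """
    S = len(histories)
    if S < 2:
        raise ValueError("need at least 2 subjects with normal and deceptive data")
    for h in histories:
        if len(h.normal_data) == 0 or len(h.deceptive_data) == 0:
            raise ValueError(f"subject {h.subject_id} lacks normal or deceptive frames")
    cfg = forest_config or ForestConfig()
    rng = as_rng(rng)
    subjects = [h.subject_id for h in histories]
    by_id = {h.subject_id: h for h in histories}
    ns = n_train_values if n_train_values is not None else list(range(1, S))
    report = EvaluationReport()

    for n_train in ns:
        if not 1 <= n_train <= S - 1:
            raise ValueError(f"n_train={n_train} out of range for cohort of {S}")
        for rep in range(repeats):
            if n_train == S - 1:
                test_ids = [subjects[rep % S]]
                train_ids = [s for s in subjects if s not in test_ids]
            else:
                perm = rng.permutation(S)
                train_ids = [subjects[i] for i in perm[:n_train]]
                test_ids = [subjects[i] for i in perm[n_train:]]

            normal_pool = LabeledFrameSet.concat([by_id[s].normal_data for s in train_ids])
            deceptive_pool = LabeledFrameSet.concat(
                [by_id[s].deceptive_data for s in train_ids]
            )
            target = len(normal_pool)
            baseline_set = balanced_bootstrap(normal_pool, None, target, rng)
            expert_set = balanced_bootstrap(normal_pool, deceptive_pool, target, rng)

            seed_b = int(rng.integers(0, 2**31 - 1))
            seed_e = int(rng.integers(0, 2**31 - 1))
            if trainer is None:
                baseline = _default_factory(cfg, seed_b)(baseline_set)
                expert = _default_factory(cfg, seed_e)(expert_set)
            else:
                baseline = trainer(baseline_set, seed_b)
                expert = trainer(expert_set, seed_e)

            test_normal = LabeledFrameSet.concat([by_id[s].normal_data for s in test_ids])
            test_deceptive = LabeledFrameSet.concat(
                [by_id[s].deceptive_data for s in test_ids]
            )
            for condition, clf in (("baseline", baseline), ("expert", expert)):
                for honesty, test in (("normal", test_normal), ("deceptive", test_deceptive)):
                    m = classification_metrics(clf.predict(test.X), test.y)
                    report.cells.append(
                        SweepCell(
                            n_train=n_train,
                            repeat=rep,
                            condition=condition,
                            honesty=honesty,
                            metrics=m,
                            train_subjects=tuple(train_ids),
                            test_subjects=tuple(test_ids),
                        )
                    )
    return report


def embed_2d(
    features: LabeledFrameSet | np.ndarray, random_state: int = 0
) -> np.ndarray:
    """2-component maximum-likelihood factor-analysis scores per frame.

    Features are standardized first; zero-variance columns are dropped. Used
    to visualize how deceptive frames cluster apart from normal frames and
    drift across trials.
    """
    X = features.X if isinstance(features, LabeledFrameSet) else np.asarray(features, float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need at least 3 rows of features")
    sd = X.std(axis=0)
    keep = sd > 1e-12
    if keep.sum() < 2:
        raise ValueError("degenerate covariance: fewer than 2 varying features")
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    fa = FactorAnalysis(n_components=2, random_state=random_state)
    return fa.fit_transform(Xs)
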