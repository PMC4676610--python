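"""The online deception trial and the iterative retraining experiment.

A *trial* streams a subject's deceptive motion past a trained classifier,
evaluating the most recent complete 4-s frame once per second; it stops when
either detected class reaches a cap (150 by default) or the 5-minute /
300-evaluation limit is hit. The *success rate* is the fraction of
evaluations whose output differed from the true activity; strictly above 50%
counts as a successful deception.

A *personal experiment* trains a classifier on one normal sitting and one
normal walking session, then loops: adapt the adversary's strategy, run a
fake-walking and a fake-sitting trial, and — if the round succeeded — fold
the deceptive frames into the training set and retrain, until the subject
fails or the round cap (10) is reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import FRAME_LEN, LabeledFrameSet, extract_dataset
from .forest import ForestConfig, VoteForestClassifier, train_forest
from .simulate import (
    SAMPLE_RATE,
    SITTING,
    WALKING,
    AdversaryConfig,
    SensorStream,
    StrategyParams,
    SubjectProfile,
    adapt_strategy,
    as_rng,
    simulate_activity,
    simulate_deceptive,
    with_preferred,
)


@dataclass
class TrialConfig:
    """Timing and stopping rules of one deceptive activity trial."""

    eval_interval_s: float = 1.0
    max_duration_s: float = 300.0
    class_count_cap: int = 150
    success_threshold: float = 0.5
    max_rounds: int = 10

    def __post_init__(self) -> None:
        if self.eval_interval_s <= 0 or self.max_duration_s <= 0:
            raise ValueError("eval_interval_s and max_duration_s must be > 0")
        if not 0.0 < self.success_threshold < 1.0:
            raise ValueError("success_threshold must lie in (0, 1)")
        if self.class_count_cap < 1 or self.max_rounds < 1:
            raise ValueError("class_count_cap and max_rounds must be >= 1")

    @property
    def max_evaluations(self) -> int:
        return int(round(self.max_duration_s / self.eval_interval_s))


@dataclass
class TrialResult:
    """Outcome of one trial, including the per-evaluation prediction log."""

    true_activity: str
    strategy: StrategyParams
    n_evaluations: int
    detected_counts: dict
    success_rate: float
    successful: bool
    eval_times: np.ndarray  # seconds, one per evaluation
    predicted: np.ndarray  # labels, one per evaluation
    confidence: np.ndarray  # vote fraction of the winning class
    frames: LabeledFrameSet  # features of the evaluated frames, truth-labeled


@dataclass
class RoundRecord:
    sitting_trial: TrialResult  # fake walking (truly seated)
    walking_trial: TrialResult  # fake sitting (truly walking)
    retrained: bool


@dataclass
class ExperimentHistory:
    """Round-by-round record of one subject's adversarial loop."""

    subject_id: str
    rounds: list[RoundRecord]
    terminal_reason: str  # "failed_round" | "max_rounds"
    normal_data: LabeledFrameSet
    deceptive_data: LabeledFrameSet  # cumulative, every trial ever run
    final_forest: VoteForestClassifier

    @property
    def n_rounds(self) -> int:
        return len(self.rounds)


@dataclass
class ExperimentConfig:
    """Everything a personal adversarial experiment needs."""

    trial: TrialConfig = field(default_factory=TrialConfig)
    adversary: AdversaryConfig = field(default_factory=AdversaryConfig)
    forest: ForestConfig = field(default_factory=ForestConfig)
    session_s: float = 300.0  # length of each normal training session
    end_rule: str = "strict"  # "strict": any failed trial ends; "lenient": both must fail
    retrain_mode: str = "cumulative"  # or "last_round"

    def __post_init__(self) -> None:
        if self.end_rule not in ("strict", "lenient"):
            raise ValueError("end_rule must be 'strict' or 'lenient'")
        if self.retrain_mode not in ("cumulative", "last_round"):
            raise ValueError("retrain_mode must be 'cumulative' or 'last_round'")


def run_trial(
    forest,
    profile: SubjectProfile,
    true_activity: str,
    strategy: StrategyParams,
    cfg: TrialConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> TrialResult:
    """Run one deceptive trial of ``strategy`` against ``forest``.

    Evaluation ``j`` (at t = 4 + j * eval_interval seconds) classifies the
    most recent complete 4-s frame; warm-up seconds before the first complete
    frame are not evaluated. Stops at the class-count cap or after
    ``max_duration_s / eval_interval_s`` evaluations, whichever comes first.
    """
    cfg = cfg or TrialConfig()
    if strategy.true_activity != true_activity:
        raise ValueError(
            f"strategy {strategy.kind!r} implies true activity "
            f"{strategy.true_activity!r}, not {true_activity!r}"
        )
    rng = as_rng(rng)
    n_max = cfg.max_evaluations
    hop_s = cfg.eval_interval_s
    frame_s = FRAME_LEN / SAMPLE_RATE
    duration = frame_s + (n_max - 1) * hop_s
    stream = simulate_deceptive(profile, strategy, duration, rng)

    hop = int(round(hop_s * SAMPLE_RATE))
    overlap = 1.0 - hop / FRAME_LEN
    fs = extract_dataset([stream], frame_len=FRAME_LEN, overlap=overlap)
    X = fs.X[:n_max]

    # predictions are per-frame and independent of the stop rule, so they can
    # be computed in one vectorized pass before scanning for the stop point
    proba = forest.predict_proba(X)
    classes = np.asarray(forest.classes_, dtype=object)
    pred_idx = np.argmax(proba, axis=1)
    counts = {str(c): 0 for c in classes}
    n_eval = 0
    for k in pred_idx:
        counts[str(classes[k])] += 1
        n_eval += 1
        if max(counts.values()) >= cfg.class_count_cap:
            break

    detected_true = counts.get(true_activity, 0)
    success_rate = 1.0 - detected_true / n_eval
    keep = slice(0, n_eval)
    return TrialResult(
        true_activity=true_activity,
        strategy=strategy,
        n_evaluations=n_eval,
        detected_counts=counts,
        success_rate=success_rate,
        successful=success_rate > cfg.success_threshold,
        eval_times=frame_s + hop_s * np.arange(n_eval),
        predicted=classes[pred_idx[keep]],
        confidence=np.max(proba[keep], axis=1),
        frames=fs.subset(np.arange(len(fs)) < n_eval),
    )


def run_personal_experiment(
    profile: SubjectProfile,
    config: ExperimentConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> ExperimentHistory:
    """Run the full adversarial retraining loop for one subject."""
    cfg = config or ExperimentConfig()
    rng = as_rng(rng)
    profile = with_preferred(profile, profile.preferred_strategies)

    def seeded() -> np.random.Generator:
        return np.random.default_rng(int(rng.integers(0, 2**31 - 1)))

    sit = simulate_activity(profile, SITTING, cfg.session_s, seeded())
    walk = simulate_activity(profile, WALKING, cfg.session_s, seeded())
    normal = extract_dataset([sit, walk])
    forest_cfg = cfg.forest

    def retrain(data: LabeledFrameSet, round_no: int):
        c = ForestConfig(
            n_trees=forest_cfg.n_trees,
            n_split_candidates=forest_cfg.n_split_candidates,
            split_criterion=forest_cfg.split_criterion,
            min_leaf=forest_cfg.min_leaf,
            max_depth=forest_cfg.max_depth,
            seed=int(rng.integers(0, 2**31 - 1)),
            bootstrap=forest_cfg.bootstrap,
        )
        return train_forest(data, c)

    forest = retrain(normal, 0)
    rounds: list[RoundRecord] = []
    deceptive_all = LabeledFrameSet.empty(normal.X.shape[1] or None)
    terminal = "max_rounds"
    adv = cfg.adversary

    for r in range(1, cfg.trial.max_rounds + 1):
        strat_fw = adapt_strategy(
            profile, forest, SITTING, adv.n_candidates, adv.probe_s, seeded(), adv
        )
        trial_sit = run_trial(forest, profile, SITTING, strat_fw, cfg.trial, seeded())
        strat_fs = adapt_strategy(
            profile, forest, WALKING, adv.n_candidates, adv.probe_s, seeded(), adv
        )
        trial_walk = run_trial(forest, profile, WALKING, strat_fs, cfg.trial, seeded())
        profile = with_preferred(profile, (strat_fw, strat_fs))

        round_frames = LabeledFrameSet.concat([trial_sit.frames, trial_walk.frames])
        deceptive_all = LabeledFrameSet.concat([deceptive_all, round_frames])

        ok = (
            trial_sit.successful and trial_walk.successful
            if cfg.end_rule == "strict"
            else trial_sit.successful or trial_walk.successful
        )
        do_retrain = ok and r < cfg.trial.max_rounds
        if do_retrain:
            extra = deceptive_all if cfg.retrain_mode == "cumulative" else round_frames
            forest = retrain(LabeledFrameSet.concat([normal, extra]), r)
        rounds.append(RoundRecord(trial_sit, trial_walk, do_retrain))
        if not ok:
            terminal = "failed_round"
            break

    return ExperimentHistory(
        subject_id=profile.subject_id,
        rounds=rounds,
        terminal_reason=terminal,
        normal_data=normal,
        deceptive_data=deceptive_all,
        final_forest=forest,
    )
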