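"""Bag-level feature selection: boosting importances and ablation curves.

The booster combines single-feature decision stumps under a noisy-OR bag
likelihood: an instance's positivity probability is the logistic of its
additive stump score, a bag is positive when any instance is, and each
round fits the stump that best follows the bag-likelihood gradient.  A
feature's importance is the normalised sum of the absolute round weights
of the stumps that used it.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from . import mil
from .bags import Bag, check_dimensions

__all__ = ["ImportanceReport", "AblationCurve", "milboost_fit", "ablation_study"]

_MAX_THRESHOLDS = 32


@dataclass
class ImportanceReport:
    """Normalised per-feature importance weights and the implied ranking."""

    weights: np.ndarray
    ranking: np.ndarray  # feature indices, most important first
    rounds_used: int
    feature_names: tuple | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.ranking = np.asarray(self.ranking, dtype=int)

    def to_tsv(self, path) -> None:
        names = self.feature_names or tuple(
            f"f{i}" for i in range(len(self.weights))
        )
        with open(path, "w") as fh:
            fh.write("feature\timportance\trank\n")
            rank_of = {int(f): r + 1 for r, f in enumerate(self.ranking)}
            for i, name in enumerate(names):
                fh.write(f"{name}\t{self.weights[i]:.6f}\t{rank_of[i]}\n")


@dataclass
class AblationCurve:
    """Mean/dispersion of F1 at each feature count, plus the chosen count."""

    counts: list[int]
    mean_f1: list[float]
    std_f1: list[float]
    stderr_f1: list[float]
    n_eval: list[int]
    chosen_count: int

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("n_features\tmean_f1\tstd_f1\tstderr_f1\tn_eval\n")
            for row in zip(self.counts, self.mean_f1, self.std_f1,
                           self.stderr_f1, self.n_eval):
                fh.write("{}\t{:.6f}\t{:.6f}\t{:.6f}\t{}\n".format(*row))


@dataclass
class _Stump:
    feature: int
    threshold: float
    polarity: int  # +1: x > thr is positive; -1: x <= thr is positive

    def __call__(self, X: np.ndarray) -> np.ndarray:
        raw = np.where(X[:, self.feature] > self.threshold, 1.0, -1.0)
        return self.polarity * raw


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def _bag_neg_log_likelihood(scores, starts, bag_labels, eps=1e-12):
    p_inst = _sigmoid(scores)
    log1m = np.log(np.clip(1.0 - p_inst, eps, None))
    prod = np.exp(np.add.reduceat(log1m, starts))  # prod_j (1 - p_ij)
    p_bag = 1.0 - prod
    lik = np.where(bag_labels > 0, p_bag, 1.0 - p_bag)
    return float(-np.log(np.clip(lik, eps, None)).sum())


def _instance_weights(scores, starts, bag_labels, bag_of, eps=1e-12):
    """d(log-likelihood)/d(score_ij) of the noisy-OR bag model."""
    p_inst = _sigmoid(scores)
    log1m = np.log(np.clip(1.0 - p_inst, eps, None))
    prod = np.exp(np.add.reduceat(log1m, starts))
    p_bag = np.clip(1.0 - prod, eps, 1.0 - eps)
    # d p_bag / d score_ij = p_ij * (1 - p_bag)
    pos = p_inst * (1.0 - p_bag[bag_of]) / p_bag[bag_of]
    neg = -p_inst
    return np.where(bag_labels[bag_of] > 0, pos, neg)


def _candidate_thresholds(column: np.ndarray) -> np.ndarray:
    values = np.unique(column)
    if len(values) < 2:
        return np.array([values[0]]) if len(values) else np.array([0.0])
    mids = (values[:-1] + values[1:]) / 2.0
    if len(mids) > _MAX_THRESHOLDS:
        take = np.linspace(0, len(mids) - 1, _MAX_THRESHOLDS).round().astype(int)
        mids = mids[np.unique(take)]
    return mids


def _best_stump(X: np.ndarray, w: np.ndarray) -> _Stump:
    """Stump maximising sum_i w_i * h(x_i); ties to lower feature index."""
    best, best_gain = None, -np.inf
    for d in range(X.shape[1]):
        col = X[:, d]
        for thr in _candidate_thresholds(col):
            raw = np.where(col > thr, 1.0, -1.0)
            gain = float(np.dot(w, raw))
            for polarity, g in ((1, gain), (-1, -gain)):
                if g > best_gain:
                    best_gain = g
                    best = _Stump(d, float(thr), polarity)
    return best


def milboost_fit(
    bags: Sequence[Bag],
    rounds: int = 50,
    seed: int = 0,
) -> ImportanceReport:
    """Rank feature importance by boosting stumps under the noisy-OR model.

    ``rounds`` must be positive and both classes must be present.  The
    procedure itself is deterministic; ``seed`` is accepted for interface
    uniformity and echoed into tie-free reproducible behaviour.
    """
    if rounds < 1:
        raise ValueError("rounds must be a positive integer")
    bag_list = list(bags)
    m = check_dimensions(bag_list)
    labels = np.array([b.label for b in bag_list])
    if any(b.label is None for b in bag_list):
        raise ValueError("all bags must be labeled")
    if not (np.any(labels > 0) and np.any(labels < 0)):
        raise ValueError("both classes are required")

    X = np.vstack([b.instances for b in bag_list])
    sizes = np.array([b.n_instances for b in bag_list])
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    bag_of = np.repeat(np.arange(len(bag_list)), sizes)

    scores = np.zeros(X.shape[0])
    alpha_per_feature = np.zeros(m)
    used_rounds = 0
    for _ in range(rounds):
        w = _instance_weights(scores, starts, labels, bag_of)
        stump = _best_stump(X, w)
        h = stump(X)
        res = minimize_scalar(
            lambda a: _bag_neg_log_likelihood(scores + a * h, starts, labels),
            bounds=(0.0, 10.0),
            method="bounded",
        )
        alpha = float(res.x)
        if not res.success or alpha <= 1e-8:
            break
        scores = scores + alpha * h
        alpha_per_feature[stump.feature] += abs(alpha)
        used_rounds += 1

    total = alpha_per_feature.sum()
    weights = (
        alpha_per_feature / total if total > 0 else np.full(m, 1.0 / m)
    )
    ranking = np.lexsort((np.arange(m), -weights))
    return ImportanceReport(weights=weights, ranking=ranking,
                            rounds_used=used_rounds)


def _default_subset_eval(sub_bags: list[Bag], seed: int,
                         model_config: mil.TrainConfig | None) -> float:
    """Small stratified CV F1 used to score one feature subset."""
    from . import evaluate  # local import: evaluate imports this package too

    cfg = model_config or mil.TrainConfig(n_restarts=2, max_iter=25)
    labels = np.array([b.label for b in sub_bags])
    folds = min(3, int(np.sum(labels > 0)), int(np.sum(labels < 0)))
    if folds < 2:
        raise ValueError("not enough bags per class for subset evaluation")
    report = evaluate.kfold_cv(
        sub_bags, k_folds=folds, K=2, pro=0.9,
        model_config=cfg, seed=seed, normalize=False,
    )
    return report.mean("f1")


def ablation_study(
    bags: Sequence[Bag],
    counts: Sequence[int] | None = None,
    subsets_per_count: int = 50,
    repeats: int = 100,
    seed: int = 0,
    eval_fn: Callable[[list[Bag], int], float] | None = None,
    model_config: mil.TrainConfig | None = None,
) -> AblationCurve:
    """Ablation over the number of features.

    For each feature count, ``subsets_per_count`` random subsets are drawn
    and each is evaluated ``ceil(repeats / subsets_per_count)`` times with
    distinct seeds; the per-count mean/std/standard-error of F1 are
    reported.  The chosen count is the smallest one whose mean F1 lies
    within one standard error of the global maximum.

    ``eval_fn(sub_bags, seed)`` may replace the default (a small CV run) to
    keep large studies affordable.
    """
    bag_list = list(bags)
    m = check_dimensions(bag_list)
    counts = sorted(set(counts)) if counts is not None else list(range(1, m + 1))
    if any(c < 1 or c > m for c in counts):
        raise ValueError(f"feature counts must lie in 1..{m}")
    rng = np.random.default_rng(seed)
    evals_per_subset = max(1, math.ceil(repeats / max(1, subsets_per_count)))
    if eval_fn is None:
        eval_fn = lambda sub, s: _default_subset_eval(sub, s, model_config)

    mean_f1, std_f1, stderr_f1, n_eval = [], [], [], []
    for count in counts:
        scores = []
        for si in range(subsets_per_count):
            subset = np.sort(rng.choice(m, size=count, replace=False))
            sub_bags = [b.with_features(subset) for b in bag_list]
            for rep in range(evals_per_subset):
                scores.append(float(eval_fn(sub_bags, seed + 7919 * si + rep)))
        scores = np.array(scores)
        mean_f1.append(float(scores.mean()))
        std_f1.append(float(scores.std()))
        stderr_f1.append(float(scores.std() / np.sqrt(len(scores))))
        n_eval.append(len(scores))

    # one-standard-error rule on the difference to the best count: the
    # smallest count whose mean is within one (combined) standard error of
    # the global maximum
    best = int(np.argmax(mean_f1))
    chosen = counts[best]
    for i, count in enumerate(counts):
        se_diff = math.sqrt(stderr_f1[i] ** 2 + stderr_f1[best] ** 2)
        if mean_f1[i] >= mean_f1[best] - se_diff:
            chosen = count
            break
    return AblationCurve(
        counts=list(counts), mean_f1=mean_f1, std_f1=std_f1,
        stderr_f1=stderr_f1, n_eval=n_eval, chosen_count=chosen,
    )
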