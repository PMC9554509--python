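"""HRD scoring: per-instance concept affinities and bag-level calls.

An instance's score is its mean affinity over the K learned concepts.  A
bag's HRD score is the maximum instance score, and the bag is called
positive exactly when some instance score reaches the learned threshold
(the existential rule: one positive LOH instance makes the sample positive).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .bags import Bag
from .mil import TrainedModel, concept_scores

__all__ = [
    "SamplePrediction",
    "instance_score",
    "classify_instance",
    "classify_bag",
    "predict_bags",
    "write_predictions",
]


@dataclass
class SamplePrediction:
    """Scored sample: continuous HRD score plus the binary status call."""

    sample_id: str
    hrd_score: float
    hrd_status: int
    instance_scores: np.ndarray

    def __post_init__(self) -> None:
        self.instance_scores = np.asarray(self.instance_scores, dtype=float)


def instance_score(x, model: TrainedModel) -> float:
    """Mean affinity of one (normalised) instance over the K concepts."""
    x = np.asarray(x, dtype=float)
    return float(concept_scores(x.reshape(1, -1), model.concept_set)[0])


def classify_instance(score: float, threshold: float) -> int:
    """+1 iff ``score >= threshold`` (the boundary is called positive)."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    return 1 if score >= threshold else -1


def classify_bag(bag: Bag, model: TrainedModel) -> SamplePrediction:
    """Score every instance and call the bag by the existential rule."""
    scores = concept_scores(bag.instances, model.concept_set)
    hrd_score = float(scores.max())
    status = 1 if hrd_score >= model.threshold else -1
    return SamplePrediction(bag.sample_id, hrd_score, status, scores)


def predict_bags(bags: Sequence[Bag], model: TrainedModel) -> list[SamplePrediction]:
    return [classify_bag(bag, model) for bag in bags]


def write_predictions(
    predictions: Sequence[SamplePrediction],
    path,
    per_instance_path=None,
    threshold: float | None = None,
) -> None:
    """Write the sample-level TSV and optionally a per-instance audit TSV.

    ``threshold`` (the model's decision threshold) is required when the
    per-instance file is requested, so each segment's call can be emitted.
    """
    with open(path, "w") as fh:
        fh.write("# hrd_score = max over per-instance concept-affinity scores\n")
        fh.write("sample_id\thrd_score\thrd_status\n")
        for pred in predictions:
            fh.write(f"{pred.sample_id}\t{pred.hrd_score:.6f}\t{pred.hrd_status}\n")
    if per_instance_path is not None:
        if threshold is None:
            raise ValueError("threshold is required for per-instance output")
        with open(per_instance_path, "w") as fh:
            fh.write("sample_id\tseg\tscore\tcall\n")
            for pred in predictions:
                for j, score in enumerate(pred.instance_scores, start=1):
                    call = classify_instance(float(score), threshold)
                    fh.write(f"{pred.sample_id}\t{j}\t{score:.6f}\t{call}\n")
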