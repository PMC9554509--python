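"""Evaluation over bags: confusion metrics, k-fold / nested CV, bootstrap.

Metrics follow the sample-level definitions: precision = TP/(TP+FP),
sensitivity = TP/(TP+FN), F1 = harmonic mean of the two.  Degenerate 0/0
denominators resolve to 0 so that aggregation never propagates NaN.
"""
from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import facets_io, mil, scoring
from .bags import Bag

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "EvalReport",
    "confusion",
    "metrics",
    "f1_score",
    "kfold_cv",
    "nested_cv",
    "bootstrap_eval",
]


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


class Metrics(NamedTuple):
    precision: float
    sensitivity: float
    f1: float


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionCounts:
    t = np.asarray(y_true)
    p = np.asarray(y_pred)
    if t.shape != p.shape:
        raise ValueError("y_true and y_pred must have the same length")
    return ConfusionCounts(
        tp=int(np.sum((t > 0) & (p > 0))),
        fp=int(np.sum((t < 0) & (p > 0))),
        fn=int(np.sum((t > 0) & (p < 0))),
        tn=int(np.sum((t < 0) & (p < 0))),
    )


def metrics(counts: ConfusionCounts) -> Metrics:
    """(precision, sensitivity, f1) with 0/0 cases resolved to 0."""
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    s = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    return Metrics(p, s, f1_score(p, s))


def f1_score(precision: float, sensitivity: float) -> float:
    """Harmonic mean of precision and sensitivity (0 when both are 0)."""
    if precision + sensitivity == 0:
        return 0.0
    return 2.0 * precision * sensitivity / (precision + sensitivity)


@dataclass
class EvalReport:
    """Per-fold (or per-replicate) metrics plus aggregates and config echo."""

    rows: list[dict] = field(default_factory=list)
    config: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def _column(self, name: str) -> np.ndarray:
        return np.array([row[name] for row in self.rows], dtype=float)

    def mean(self, name: str) -> float:
        col = self._column(name)
        return float(col.mean()) if len(col) else 0.0

    def variance(self, name: str) -> float:
        col = self._column(name)
        return float(col.var()) if len(col) else 0.0

    def summary(self) -> dict:
        out = {"n_rows": len(self.rows)}
        for name in ("precision", "sensitivity", "f1"):
            out[f"mean_{name}"] = self.mean(name)
            out[f"var_{name}"] = self.variance(name)
        return out

    def to_json(self, path) -> None:
        import json

        doc = {
            "summary": self.summary(),
            "rows": self.rows,
            "config": self.config,
            "extras": self.extras,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, default=str)
            fh.write("\n")

    def to_tsv(self, path) -> None:
        if not self.rows:
            raise ValueError("empty report")
        cols = list(self.rows[0])
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for row in self.rows:
                fh.write("\t".join(str(row[c]) for c in cols) + "\n")


def _normalize_split(train_bags: list[Bag], test_bags: list[Bag]):
    """Fit min-max bounds on the training bags only; clip the test bags."""
    stacked = np.vstack([b.instances for b in train_bags])
    bounds = facets_io.fit_minmax(stacked)
    norm = lambda b: Bag(
        b.sample_id, facets_io.apply_minmax(b.instances, bounds), b.label
    )
    return [norm(b) for b in train_bags], [norm(b) for b in test_bags], bounds


def _fit_predict(
    train_bags: list[Bag],
    test_bags: list[Bag],
    K: int,
    pro: float,
    seed: int,
    model_config: mil.TrainConfig | None,
    normalize: bool,
):
    if normalize:
        train_bags, test_bags, bounds = _normalize_split(train_bags, test_bags)
    else:
        bounds = None
    model = mil.train(train_bags, K=K, pro=pro, seed=seed, config=model_config,
                      bounds=bounds)
    preds = scoring.predict_bags(test_bags, model)
    y_true = np.array([b.label for b in test_bags])
    y_pred = np.array([p.hrd_status for p in preds])
    return y_true, y_pred


def _check_both_classes(bags: Sequence[Bag]) -> np.ndarray:
    labels = np.array([b.label for b in bags])
    if any(label is None for label in labels):
        raise ValueError("all bags must be labeled for evaluation")
    if not (np.any(labels > 0) and np.any(labels < 0)):
        raise ValueError("evaluation requires both classes")
    return labels


def kfold_cv(
    bags: Sequence[Bag],
    k_folds: int = 10,
    K: int = 3,
    pro: float = 0.9,
    model_config: mil.TrainConfig | None = None,
    seed: int = 0,
    normalize: bool = True,
) -> EvalReport:
    """Stratified k-fold cross-validation over whole bags.

    Bags are never split across folds; normalisation bounds are re-fit on
    each training fold.  Deterministic given ``seed``.
    """
    bag_list = list(bags)
    labels = _check_both_classes(bag_list)
    if len(bag_list) < k_folds:
        raise ValueError(
            f"need at least {k_folds} bags for {k_folds}-fold CV, got {len(bag_list)}"
        )
    splitter = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    report = EvalReport(config={
        "mode": "kfold", "k_folds": k_folds, "K": K, "pro": pro, "seed": seed,
    })
    for fold, (tr, te) in enumerate(splitter.split(np.zeros(len(bag_list)), labels)):
        y_true, y_pred = _fit_predict(
            [bag_list[i] for i in tr],
            [bag_list[i] for i in te],
            K, pro, seed + fold + 1, model_config, normalize,
        )
        m = metrics(confusion(y_true, y_pred))
        report.rows.append({
            "fold": fold,
            "n_test": len(te),
            "precision": m.precision,
            "sensitivity": m.sensitivity,
            "f1": m.f1,
        })
    return report


def nested_cv(
    bags: Sequence[Bag],
    outer_folds: int = 5,
    inner_folds: int = 3,
    K_grid: Sequence[int] = (1, 2, 3, 4),
    pro_grid: Sequence[float] = (0.9,),
    model_config: mil.TrainConfig | None = None,
    seed: int = 0,
    normalize: bool = True,
) -> EvalReport:
    """Nested CV: inner loop picks (K, pro) by mean F1, outer loop scores it.

    The report's ``extras`` carries the per-fold chosen hyperparameters and
    the absolute difference of the nested means versus a plain k-fold run
    with the modal chosen configuration.
    """
    if not K_grid or not pro_grid:
        raise ValueError("hyperparameter grids must be non-empty")
    bag_list = list(bags)
    labels = _check_both_classes(bag_list)
    outer = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=seed)
    report = EvalReport(config={
        "mode": "nested", "outer_folds": outer_folds, "inner_folds": inner_folds,
        "K_grid": list(K_grid), "pro_grid": list(pro_grid), "seed": seed,
    })
    chosen_configs = []
    for fold, (tr, te) in enumerate(outer.split(np.zeros(len(bag_list)), labels)):
        train_bags = [bag_list[i] for i in tr]
        candidates = []  # (K, pro, mean f1, stderr)
        for K in sorted(K_grid):
            for pro in pro_grid:
                try:
                    inner = kfold_cv(
                        train_bags, k_folds=inner_folds, K=K, pro=pro,
                        model_config=model_config, seed=seed + 1000 * (fold + 1),
                        normalize=normalize,
                    )
                except ValueError as exc:
                    warnings.warn(
                        f"outer fold {fold}: skipping K={K}, pro={pro}: {exc}"
                    )
                    continue
                stderr = float(
                    np.sqrt(inner.variance("f1") / max(len(inner.rows), 1))
                )
                candidates.append((K, pro, inner.mean("f1"), stderr))
        if not candidates:
            raise ValueError(f"outer fold {fold}: no feasible hyperparameters")
        # one-standard-error parsimony: among candidates within one stderr of
        # the best mean, prefer the smallest K (then the larger pro)
        best_mean, best_se = max((c[2], c[3]) for c in candidates)
        viable = [c for c in candidates if c[2] >= best_mean - best_se]
        K, pro, best_score, _ = min(viable, key=lambda c: (c[0], -c[1]))
        chosen_configs.append({"fold": fold, "K": K, "pro": pro,
                               "inner_f1": best_score})
        y_true, y_pred = _fit_predict(
            train_bags, [bag_list[i] for i in te],
            K, pro, seed + fold + 1, model_config, normalize,
        )
        m = metrics(confusion(y_true, y_pred))
        report.rows.append({
            "fold": fold, "n_test": len(te), "K": K, "pro": pro,
            "precision": m.precision, "sensitivity": m.sensitivity, "f1": m.f1,
        })
    report.extras["chosen"] = chosen_configs
    # compare with a plain k-fold run at the modal chosen configuration
    modal_K, modal_pro = Counter(
        (c["K"], c["pro"]) for c in chosen_configs
    ).most_common(1)[0][0]
    plain = kfold_cv(
        bag_list, k_folds=outer_folds, K=modal_K, pro=modal_pro,
        model_config=model_config, seed=seed, normalize=normalize,
    )
    report.extras["modal_config"] = {"K": modal_K, "pro": modal_pro}
    report.extras["abs_diff_vs_kfold"] = {
        name: abs(report.mean(name) - plain.mean(name))
        for name in ("precision", "sensitivity", "f1")
    }
    return report


def bootstrap_eval(
    bags: Sequence[Bag],
    replicates: int = 500,
    K: int = 3,
    pro: float = 0.9,
    model_config: mil.TrainConfig | None = None,
    seed: int = 0,
    normalize: bool = True,
    max_retries: int = 10,
) -> EvalReport:
    """Bootstrap over bags: resample with replacement, score the out-of-bag.

    Replicates whose resample lacks a class (or has no out-of-bag samples)
    are redrawn up to ``max_retries`` times, then skipped with a warning.
    """
    bag_list = list(bags)
    _check_both_classes(bag_list)
    rng = np.random.default_rng(seed)
    n = len(bag_list)
    report = EvalReport(config={
        "mode": "bootstrap", "replicates": replicates, "K": K, "pro": pro,
        "seed": seed,
    })
    skipped = 0
    for rep in range(replicates):
        ok = False
        for _ in range(max_retries):
            idx = rng.integers(0, n, size=n)
            train_bags = [bag_list[i] for i in idx]
            oob = sorted(set(range(n)) - set(idx.tolist()))
            labels = np.array([b.label for b in train_bags])
            if oob and np.any(labels > 0) and np.any(labels < 0):
                ok = True
                break
        if not ok:
            warnings.warn(f"replicate {rep}: could not draw a usable resample")
            skipped += 1
            continue
        y_true, y_pred = _fit_predict(
            train_bags, [bag_list[i] for i in oob],
            K, pro, seed + rep + 1, model_config, normalize,
        )
        m = metrics(confusion(y_true, y_pred))
        report.rows.append({
            "replicate": rep, "n_oob": len(oob),
            "precision": m.precision, "sensitivity": m.sensitivity, "f1": m.f1,
        })
    report.extras["skipped"] = skipped
    return report
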