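"""Multi-instance learning core: diverse-density EM over K concept points.

The model learns K "target concept" locations in normalised LOH feature
space.  An instance's affinity to a concept ``t`` under per-feature scales
``s`` is the squared-exponential

    sim(x, t) = exp(-sum_d (s_d * (x_d - t_d))**2)

A positive bag's likelihood under a concept is the affinity of its closest
instance (most-likely-cause); a negative bag's is one minus that.  The
training objective is the per-concept-averaged negative log likelihood
(``nnldd``), minimised by alternating an E-step (pick one representative
instance per bag per concept) and an M-step (re-optimise each concept over
its representatives with a quasi-Newton solver).
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

from .bags import Bag, check_dimensions
from .facets_io import DEFAULT_FEATURES, NormalizationBounds

__all__ = [
    "ConceptSet",
    "RepresentativeSet",
    "TrainConfig",
    "TrainedModel",
    "instance_similarity",
    "bag_likelihood",
    "nnldd",
    "set_nnldd",
    "e_step",
    "m_step",
    "train",
]

EPS = 1e-12
MODEL_FORMAT_VERSION = 1
#: Box constraints for concept locations in normalised feature space.
CONCEPT_BOX = (-0.5, 1.5)


@dataclass
class ConceptSet:
    """K concept locations plus the shared per-feature scale weights."""

    concepts: np.ndarray  # (K, m)
    scales: np.ndarray  # (m,)

    def __post_init__(self) -> None:
        self.concepts = np.atleast_2d(np.asarray(self.concepts, dtype=float))
        self.scales = np.asarray(self.scales, dtype=float)
        if self.concepts.shape[0] < 1:
            raise ValueError("at least one concept is required")
        if self.scales.ndim != 1 or self.scales.shape[0] != self.concepts.shape[1]:
            raise ValueError("scales must match the concept dimension")
        if np.any(self.scales <= 0):
            raise ValueError("scales must be strictly positive")

    @property
    def K(self) -> int:
        return self.concepts.shape[0]

    @property
    def n_features(self) -> int:
        return self.concepts.shape[1]

    @classmethod
    def with_unit_scales(cls, concepts) -> "ConceptSet":
        concepts = np.atleast_2d(np.asarray(concepts, dtype=float))
        return cls(concepts, np.ones(concepts.shape[1]))


@dataclass
class RepresentativeSet:
    """E-step output: one chosen instance per (concept, bag).

    ``indices[k, i]`` is the instance index selected in bag ``i`` for
    concept ``k``; ``probs`` its affinity; ``reliable`` marks affinities
    strictly above the Pro threshold.  ``bag_scores`` is the per-bag mean
    affinity across concepts (the bag-level candidate score).
    """

    indices: np.ndarray
    probs: np.ndarray
    reliable: np.ndarray
    bag_scores: np.ndarray


@dataclass
class TrainConfig:
    """Knobs for the EM trainer (everything except K, pro and seed)."""

    n_restarts: int = 5
    tol: float = 1e-4
    max_iter: int = 100
    optimize_scales: bool = False
    init_min_dist: float = 0.2
    max_candidates: int = 2000
    eps: float = EPS


@dataclass
class TrainedModel:
    """A fitted model: concepts, decision threshold and preprocessing state."""

    concept_set: ConceptSet
    threshold: float
    pro: float
    bounds: NormalizationBounds
    feature_names: tuple
    training_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")
        if not (0.0 < self.pro < 1.0):
            raise ValueError("pro must lie in (0, 1)")
        if self.concept_set.n_features != len(self.feature_names):
            raise ValueError("concept dimension does not match feature names")

    def to_dict(self) -> dict:
        return {
            "format_version": MODEL_FORMAT_VERSION,
            "concepts": self.concept_set.concepts.tolist(),
            "scales": self.concept_set.scales.tolist(),
            "threshold": self.threshold,
            "pro": self.pro,
            "bounds": {
                "minimum": self.bounds.minimum.tolist(),
                "maximum": self.bounds.maximum.tolist(),
            },
            "feature_names": list(self.feature_names),
            "training_log": self.training_log,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_dict(cls, doc: dict) -> "TrainedModel":
        version = doc.get("format_version")
        if version != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format version: {version!r}")
        return cls(
            concept_set=ConceptSet(np.array(doc["concepts"]), np.array(doc["scales"])),
            threshold=float(doc["threshold"]),
            pro=float(doc["pro"]),
            bounds=NormalizationBounds(
                np.array(doc["bounds"]["minimum"]),
                np.array(doc["bounds"]["maximum"]),
            ),
            feature_names=tuple(doc["feature_names"]),
            training_log=doc.get("training_log", {}),
        )

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# similarity / likelihood primitives


def instance_similarity(x, t, s) -> float:
    """exp(-sum_d (s_d * (x_d - t_d))**2); 1 iff x == t."""
    x = np.asarray(x, dtype=float)
    t = np.asarray(t, dtype=float)
    s = np.asarray(s, dtype=float)
    if x.shape != t.shape or x.shape != s.shape:
        raise ValueError("x, t and s must have identical dimensions")
    if np.any(s <= 0):
        raise ValueError("scales must be strictly positive")
    return float(np.exp(-np.sum((s * (x - t)) ** 2)))


def _sims(X: np.ndarray, t: np.ndarray, s: np.ndarray) -> np.ndarray:
    return np.exp(-np.sum(((X - t) * s) ** 2, axis=1))


def bag_likelihood(bag: Bag, t, s) -> float:
    """Most-likely-cause bag likelihood under one concept.

    Positive bag: max instance similarity; negative bag: 1 - that max.
    """
    if bag.label is None:
        raise ValueError(f"bag {bag.sample_id!r} is unlabeled")
    t = np.asarray(t, dtype=float)
    s = np.asarray(s, dtype=float)
    best = float(_sims(bag.instances, t, s).max())
    return best if bag.label > 0 else 1.0 - best


def nnldd(concept_set: ConceptSet, bags: Sequence[Bag], eps: float = EPS) -> float:
    """Negative log diverse density averaged over concepts; lower is better."""
    if concept_set.K < 1:
        raise ValueError("need at least one concept")
    total = 0.0
    for t in concept_set.concepts:
        for bag in bags:
            lik = bag_likelihood(bag, t, concept_set.scales)
            total += -np.log(max(lik, eps))
    return total / concept_set.K


def set_nnldd(concept_set: ConceptSet, bags: Sequence[Bag], eps: float = EPS) -> float:
    """Negative log diverse density of the concept *set* as a whole.

    Under the existential bag rule a positive bag is explained by its best
    concept, so the set-level likelihood of a bag uses the maximum
    bag/concept affinity over the K concepts (complement for negatives).
    Unlike :func:`nnldd`, which averages independent per-concept terms, this
    criterion rewards a set whose concepts jointly cover all positive bags;
    it is used to pick between restarts.  For K=1 it equals :func:`nnldd`.
    """
    total = 0.0
    for bag in bags:
        if bag.label is None:
            raise ValueError(f"bag {bag.sample_id!r} is unlabeled")
        best = max(
            float(_sims(bag.instances, t, concept_set.scales).max())
            for t in concept_set.concepts
        )
        lik = best if bag.label > 0 else 1.0 - best
        total += -np.log(max(lik, eps))
    return total


# ---------------------------------------------------------------------------
# stacked-view helpers


class _BagData:
    """Flat view of a bag list for vectorised similarity computations."""

    def __init__(self, bags: Sequence[Bag]):
        self.bags = list(bags)
        self.n_bags = len(self.bags)
        check_dimensions(self.bags)
        self.X = np.vstack([b.instances for b in self.bags])
        sizes = np.array([b.n_instances for b in self.bags])
        self.starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
        self.labels = np.array(
            [0 if b.label is None else b.label for b in self.bags]
        )

    def bag_max(self, sims: np.ndarray) -> np.ndarray:
        return np.maximum.reduceat(sims, self.starts)

    def bag_argmax(self, sims: np.ndarray):
        """Per-bag (argmax index, max value); ties go to the lowest index."""
        idx = np.empty(self.n_bags, dtype=int)
        val = np.empty(self.n_bags)
        bounds = np.append(self.starts, len(sims))
        for i in range(self.n_bags):
            chunk = sims[bounds[i]:bounds[i + 1]]
            j = int(np.argmax(chunk))
            idx[i] = j
            val[i] = chunk[j]
        return idx, val


def _candidate_nnldd(data: _BagData, candidates: np.ndarray, s: np.ndarray,
                     eps: float) -> np.ndarray:
    """Single-concept NNLDD of every candidate location, vectorised."""
    sq = cdist(data.X * s, candidates * s, "sqeuclidean")
    sims = np.exp(-sq)  # (N, C)
    maxs = np.maximum.reduceat(sims, data.starts, axis=0)  # (n_bags, C)
    lik = np.where(data.labels[:, None] > 0, maxs, 1.0 - maxs)
    return -np.log(np.clip(lik, eps, None)).sum(axis=0)


def concept_scores(X: np.ndarray, concept_set: ConceptSet) -> np.ndarray:
    """Mean affinity of each row of X over all concepts (instance scores)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != concept_set.n_features:
        raise ValueError(
            f"dimension mismatch: instances have {X.shape[1]} features, "
            f"concepts have {concept_set.n_features}"
        )
    total = np.zeros(X.shape[0])
    for t in concept_set.concepts:
        total += _sims(X, t, concept_set.scales)
    return total / concept_set.K


# ---------------------------------------------------------------------------
# EM steps


def e_step(concept_set: ConceptSet, bags: Sequence[Bag], pro: float) -> RepresentativeSet:
    """Select the most probable instance per bag for every concept.

    Representatives with affinity strictly above ``pro`` are marked
    reliable; ties on the maximum go to the lowest instance index.
    """
    if not (0.0 < pro < 1.0):
        raise ValueError("pro must lie in (0, 1)")
    data = bags if isinstance(bags, _BagData) else _BagData(bags)
    K = concept_set.K
    indices = np.empty((K, data.n_bags), dtype=int)
    probs = np.empty((K, data.n_bags))
    for k, t in enumerate(concept_set.concepts):
        sims = _sims(data.X, t, concept_set.scales)
        indices[k], probs[k] = data.bag_argmax(sims)
    return RepresentativeSet(
        indices=indices,
        probs=probs,
        reliable=probs > pro,
        bag_scores=probs.mean(axis=0),
    )


def _reduced_objective(t, R, labels, s, eps):
    d = np.sum(((R - t) * s) ** 2, axis=1)
    e = np.exp(-d)
    lik = np.where(labels > 0, e, 1.0 - e)
    return float(-np.log(np.clip(lik, eps, None)).sum())


def _reduced_gradient(t, R, labels, s, eps):
    diff = (t - R) * s**2  # (n, m), already scaled
    d = np.sum(((R - t) * s) ** 2, axis=1)
    e = np.exp(-d)
    # positive bags: d/dt of d_i = 2*s^2*(t - R_i)
    # negative bags: d/dt of -log(1-e) = -e/(1-e) * 2*s^2*(t - R_i)
    coef = np.where(labels > 0, 1.0, -e / np.clip(1.0 - e, eps, None))
    return 2.0 * (coef[:, None] * diff).sum(axis=0)


def _reduced_set(concept_k: int, reps: RepresentativeSet, bag_list, labels):
    """Concept k's reduced dataset: reliable representatives only.

    Representatives whose affinity does not exceed the Pro threshold are
    segments unrelated to this concept's cluster (or false-positive LOH
    calls) and are filtered out.  If no positive representative is reliable
    the concept falls back to all positive representatives so the E/M
    alternation can still make progress.
    """
    R = np.vstack(
        [bag_list[i].instances[reps.indices[concept_k, i]]
         for i in range(len(bag_list))]
    )
    keep = reps.reliable[concept_k].copy()
    if not np.any(keep & (labels > 0)):
        keep |= labels > 0
    return R[keep], labels[keep]


def m_step(
    concept_set: ConceptSet,
    reps: RepresentativeSet,
    bags: Sequence[Bag],
    config: TrainConfig | None = None,
) -> ConceptSet:
    """Re-optimise each concept over its reliable reduced dataset.

    Uses box-constrained L-BFGS-B on the concept's negative log diverse
    density over the reliable representatives (see :func:`_reduced_set`);
    a concept is only replaced when the objective strictly improves, so the
    reduced-set NNLDD never increases.  When a concept's reduced positive
    and negative representatives coincide exactly the objective carries no
    usable signal and the concept is returned unchanged.
    """
    cfg = config or TrainConfig()
    bag_list = bags.bags if isinstance(bags, _BagData) else list(bags)
    labels = np.array([b.label for b in bag_list])
    if np.any(labels == None):  # noqa: E711 - catches unlabeled bags
        raise ValueError("all bags must be labeled for the M-step")
    s = concept_set.scales
    box = [CONCEPT_BOX] * concept_set.n_features
    new_concepts = np.empty_like(concept_set.concepts)
    for k in range(concept_set.K):
        R, rlabels = _reduced_set(k, reps, bag_list, labels)
        t0 = concept_set.concepts[k]
        pos_rows = {tuple(r) for r in R[rlabels > 0]}
        neg_rows = {tuple(r) for r in R[rlabels < 0]}
        if pos_rows and pos_rows == neg_rows:
            new_concepts[k] = t0  # contradictory reduced set: no signal
            continue
        args = (R, rlabels, s, cfg.eps)
        f0 = _reduced_objective(t0, *args)
        try:
            res = minimize(
                _reduced_objective,
                t0,
                args=args,
                jac=_reduced_gradient,
                method="L-BFGS-B",
                bounds=box,
            )
        except Exception as exc:  # pragma: no cover - defensive
            warnings.warn(f"concept {k}: optimizer failed ({exc}); keeping input")
            new_concepts[k] = t0
            continue
        if res.success and res.fun < f0:
            new_concepts[k] = res.x
        else:
            if not res.success:
                warnings.warn(
                    f"concept {k}: optimizer did not converge; keeping input"
                )
            new_concepts[k] = t0
    scales = s
    if cfg.optimize_scales:
        scales = _optimize_scales(new_concepts, reps, bag_list, labels, s, cfg)
    return ConceptSet(new_concepts, scales)


def _optimize_scales(concepts, reps, bag_list, labels, s, cfg):
    """Optionally re-fit the shared log-scales over all reduced datasets."""
    sets = [
        _reduced_set(k, reps, bag_list, labels)
        for k in range(concepts.shape[0])
    ]

    def obj(log_s):
        sv = np.exp(log_s)
        return sum(
            _reduced_objective(concepts[k], sets[k][0], sets[k][1], sv, cfg.eps)
            for k in range(concepts.shape[0])
        )

    res = minimize(obj, np.log(s), method="L-BFGS-B",
                   bounds=[(-5.0, 5.0)] * len(s))
    if res.success and res.fun < obj(np.log(s)):
        return np.exp(res.x)
    return s


# ---------------------------------------------------------------------------
# initialisation and training loop


def _ordered_candidates(data: _BagData, s, cfg, rng):
    """Positive-bag instances ranked by single-concept NNLDD (best first).

    Ties are broken by lexicographic comparison of the candidate's
    coordinates so the ranking is independent of bag/instance order.
    """
    pos_rows = np.concatenate([
        np.arange(data.starts[i],
                  data.starts[i] + data.bags[i].n_instances)
        for i in range(data.n_bags) if data.labels[i] > 0
    ])
    cands = data.X[pos_rows]
    if len(cands) > cfg.max_candidates:
        pick = rng.choice(len(cands), size=cfg.max_candidates, replace=False)
        cands = cands[np.sort(pick)]
    dd = _candidate_nnldd(data, cands, s, cfg.eps)
    keys = tuple(cands[:, j] for j in range(cands.shape[1] - 1, -1, -1)) + (dd,)
    order = np.lexsort(keys)
    return cands[order], dd[order]


def _greedy_cover_init(
    data: _BagData, cands: np.ndarray, K: int, min_dist: float, eps: float
) -> np.ndarray:
    """Greedy coverage initialisation: minimise the set-level NNLDD.

    Candidates are added one at a time, each pick being the one that most
    improves the joint (existential-rule) likelihood given the concepts
    already chosen — so bags unexplained by earlier picks drive later
    picks toward the remaining clusters.  Ties resolve to the first
    candidate in ranked order; the pairwise distance constraint is relaxed
    by halving when it cannot be met.
    """
    sq = cdist(data.X, cands, "sqeuclidean")
    M = np.maximum.reduceat(np.exp(-sq), data.starts, axis=0)  # (n_bags, C)
    pos = data.labels > 0
    chosen: list[int] = []
    cur = np.zeros(data.n_bags)
    dist = min_dist
    while len(chosen) < K:
        cover = np.maximum(cur[:, None], M)  # (n_bags, C)
        lik = np.where(pos[:, None], cover, 1.0 - cover)
        objective = -np.log(np.clip(lik, eps, None)).sum(axis=0)
        if chosen:
            far = np.ones(len(cands), dtype=bool)
            for j in chosen:
                far &= np.linalg.norm(cands - cands[j], axis=1) >= dist
            if not np.any(far):
                if dist < 1e-9:
                    chosen.append(chosen[-1])
                    continue
                dist /= 2.0
                continue
            objective = np.where(far, objective, np.inf)
        pick = int(np.argmin(objective))
        chosen.append(pick)
        cur = np.maximum(cur, M[:, pick])
    return cands[chosen]


def _greedy_pick(cands: np.ndarray, order: np.ndarray, K: int, min_dist: float):
    """First K candidates in `order` subject to pairwise L2 >= min_dist."""
    while True:
        chosen: list[int] = []
        for i in order:
            if all(
                np.linalg.norm(cands[i] - cands[j]) >= min_dist for j in chosen
            ):
                chosen.append(int(i))
                if len(chosen) == K:
                    return cands[chosen]
        if min_dist < 1e-9:
            # fewer distinct candidates than K: repeat the best ones
            reps = [int(order[i % len(order)]) for i in range(K)]
            return cands[reps]
        min_dist /= 2.0


def _select_threshold(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Training-F1-maximising threshold over the sorted bag scores.

    Ties prefer the higher threshold (fewer positive calls).  Returns
    (threshold, best F1).
    """
    best_thr, best_f1 = None, -1.0
    for thr in np.unique(scores):
        pred = np.where(scores >= thr, 1, -1)
        f1 = _f1(labels, pred)
        if f1 > best_f1 or (f1 == best_f1 and (best_thr is None or thr > best_thr)):
            best_f1, best_thr = f1, float(thr)
    thr = min(max(best_thr, 1e-12), float(np.nextafter(1.0, 0.0)))
    return thr, best_f1


def _f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    tp = int(np.sum((y_true > 0) & (y_pred > 0)))
    fp = int(np.sum((y_true < 0) & (y_pred > 0)))
    fn = int(np.sum((y_true > 0) & (y_pred < 0)))
    p = tp / (tp + fp) if tp + fp else 0.0
    s = tp / (tp + fn) if tp + fn else 0.0
    return 2 * p * s / (p + s) if p + s else 0.0


def train(
    bags: Sequence[Bag],
    K: int = 3,
    pro: float = 0.9,
    seed: int = 0,
    config: TrainConfig | None = None,
    bounds: NormalizationBounds | None = None,
    feature_names: Sequence[str] | None = None,
) -> TrainedModel:
    """Fit K concept points by alternating E- and M-steps from restarts.

    Bags must contain normalised feature vectors and at least one bag of
    each class.  Restart 0 is a greedy coverage initialisation; further
    restarts draw from the top-ranked candidate instances.  The restart
    with the lowest final set-level NNLDD wins (the per-concept-averaged
    NNLDD cannot tell a covering concept set from K copies of one
    concept), and the decision threshold is the training-F1 maximiser over
    bag scores.  Deterministic given ``seed``.
    """
    cfg = config or TrainConfig()
    bag_list = list(bags)
    m = check_dimensions(bag_list)
    labels = np.array([b.label for b in bag_list])
    if any(b.label is None for b in bag_list):
        raise ValueError("all training bags must be labeled")
    n_pos_bags = int(np.sum(labels > 0))
    n_neg_bags = int(np.sum(labels < 0))
    if n_pos_bags == 0 or n_neg_bags == 0:
        raise ValueError("training requires both positive and negative bags")
    if K < 1:
        raise ValueError("K must be at least 1")
    total_pos_instances = sum(
        b.n_instances for b in bag_list if b.label > 0
    )
    if K > total_pos_instances:
        raise ValueError(
            f"K={K} exceeds the {total_pos_instances} positive-bag instances"
        )
    if not (0.0 < pro < 1.0):
        raise ValueError("pro must lie in (0, 1)")

    rng = np.random.default_rng(seed)
    data = _BagData(bag_list)
    scales = np.ones(m)
    cands, _dd = _ordered_candidates(data, scales, cfg, rng)
    n_cands = len(cands)
    top_q = min(n_cands, max(50, 5 * K))

    best = None  # (set_nnldd, restart, ConceptSet, iterations, converged)
    restart_nnldds = []
    for r in range(max(1, cfg.n_restarts)):
        if r == 0:
            init = _greedy_cover_init(data, cands, K, cfg.init_min_dist, cfg.eps)
        else:
            order = rng.permutation(top_q)
            init = _greedy_pick(cands, order, K, cfg.init_min_dist)
        cs = ConceptSet(init.copy(), scales.copy())
        converged = False
        iterations = 0
        for it in range(cfg.max_iter):
            iterations = it + 1
            reps = e_step(cs, data, pro)
            new_cs = m_step(cs, reps, data, cfg)
            delta = float(np.max(np.abs(new_cs.concepts - cs.concepts)))
            cs = new_cs
            if delta < cfg.tol:
                converged = True
                break
        final = set_nnldd(cs, bag_list, cfg.eps)
        restart_nnldds.append(final)
        if best is None or final < best[0]:
            best = (final, r, cs, iterations, converged)

    final_set_nnldd, best_restart, cs, iterations, converged = best
    reps = e_step(cs, data, pro)
    # per-concept product of representative affinities (selection diagnostic)
    rep_products = np.prod(reps.probs, axis=1)

    scores = np.maximum.reduceat(concept_scores(data.X, cs), data.starts)
    threshold, train_f1 = _select_threshold(scores, labels)

    if bounds is None:
        bounds = NormalizationBounds.unit(m)
    if feature_names is None:
        feature_names = DEFAULT_FEATURES if m == len(DEFAULT_FEATURES) else tuple(
            f"f{i}" for i in range(m)
        )

    log = {
        "seed": int(seed),
        "K": int(K),
        "n_restarts": int(max(1, cfg.n_restarts)),
        "best_restart": int(best_restart),
        "iterations": int(iterations),
        "converged": bool(converged),
        "final_nnldd": float(nnldd(cs, bag_list, cfg.eps)),
        "final_set_nnldd": float(final_set_nnldd),
        "restart_set_nnldds": [float(v) for v in restart_nnldds],
        "rep_prob_product": [float(v) for v in rep_products],
        "reliable_fraction": float(reps.reliable.mean()),
        "train_f1": float(train_f1),
    }
    return TrainedModel(
        concept_set=cs,
        threshold=threshold,
        pro=pro,
        bounds=bounds,
        feature_names=tuple(feature_names),
        training_log=log,
    )
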