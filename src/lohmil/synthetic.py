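"""Synthetic labeled bags and FACETS-dialect tables with planted concepts.

Positive bags mix uniform background segments with "signal" segments drawn
from clipped Gaussians centred on planted concept locations; negative bags
contain background only.  The generator also writes its bags back out as
per-sample cncf TSVs so the whole I/O + training pipeline can be exercised
without external data.
"""
from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import facets_io
from .bags import Bag
from .facets_io import DEFAULT_FEATURES, NormalizationBounds, SegmentRecord

__all__ = ["SimConfig", "SimTruth", "simulate_bags", "bags_to_cncf", "RAW_RANGES"]

#: Plausible raw value ranges used to de-normalise the nine features.
#: start/end ranges are disjoint so that start <= end always holds, and
#: lcn.em's range sits below tcn.em's so that lcn <= tcn always holds.
RAW_RANGES = {
    "nhet": (0.0, 1_000_000.0),
    "cnlr_median": (-2.5, 2.5),
    "mafR": (0.0, 12.0),
    "mafR_clust": (0.0, 12.0),
    "start": (1_000_000.0, 50_000_000.0),
    "end": (60_000_000.0, 110_000_000.0),
    "cf_em": (0.01, 1.0),
    "tcn_em": (2.0, 10.0),
    "lcn_em": (0.0, 2.0),
}

_INT_RAW = {"nhet", "start", "end"}


@dataclass
class SimConfig:
    """Generator settings; all randomness flows from ``seed``."""

    n_pos: int = 28
    n_neg: int = 28
    k_true: int = 3
    concept_locations: np.ndarray | None = None  # (k_true, n_features) or None
    concept_spread: float = 0.03
    instances_per_bag: tuple[int, int] = (3, 30)
    signal_per_positive: tuple[int, int] = (1, 3)
    label_noise: float = 0.0
    n_features: int = 9
    min_concept_separation: float = 1.0  # L2, when locations are random
    background_exclusion: float = 0.8  # L2 radius around concepts kept clear
    seed: int = 7

    def __post_init__(self) -> None:
        if self.k_true < 1:
            raise ValueError("k_true must be at least 1")
        if self.concept_spread <= 0:
            raise ValueError("concept_spread must be positive")
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("bag counts must be at least 1")
        if self.signal_per_positive[0] < 1:
            raise ValueError("positive bags need at least one signal instance")
        if not (0.0 <= self.label_noise < 1.0):
            raise ValueError("label_noise must lie in [0, 1)")
        if self.concept_locations is not None:
            locs = np.atleast_2d(np.asarray(self.concept_locations, dtype=float))
            if locs.shape != (self.k_true, self.n_features):
                raise ValueError(
                    f"concept_locations must have shape "
                    f"({self.k_true}, {self.n_features})"
                )
            self.concept_locations = locs


@dataclass
class SimTruth:
    """Ground truth of a simulation run."""

    concepts: np.ndarray  # (k_true, n_features)
    signal_flags: dict = field(default_factory=dict)  # sample_id -> bool array
    concept_of: dict = field(default_factory=dict)  # sample_id -> int array (-1 = bg)
    labels_pre_noise: dict = field(default_factory=dict)  # sample_id -> +1/-1
    seed: int = 0


def _random_concepts(rng: np.random.Generator, cfg: SimConfig) -> np.ndarray:
    """Draw k_true well-separated concept locations in [0.1, 0.9]^m."""
    for _ in range(1000):
        locs = rng.uniform(0.1, 0.9, size=(cfg.k_true, cfg.n_features))
        ok = True
        for a in range(cfg.k_true):
            for b in range(a + 1, cfg.k_true):
                if np.linalg.norm(locs[a] - locs[b]) < cfg.min_concept_separation:
                    ok = False
        if ok:
            return locs
    raise RuntimeError("could not place well-separated concepts; lower "
                       "min_concept_separation or k_true")


def _background(rng: np.random.Generator, n: int, concepts: np.ndarray,
                cfg: SimConfig) -> np.ndarray:
    """Uniform background segments kept clear of the planted clusters.

    Background rows model LOHs unrelated to HRD, so they are rejection
    sampled to lie at least ``background_exclusion`` (L2) away from every
    planted concept; with fully uniform background at realistic bag sizes
    some unrelated segment of nearly every bag would fall arbitrarily
    close to each cluster and the planted structure would be
    unidentifiable from bag labels alone.
    """
    if n == 0:
        return np.empty((0, cfg.n_features))
    out = np.empty((n, cfg.n_features))
    filled = 0
    for _ in range(1000):
        draw = rng.uniform(0.0, 1.0, size=(max(n - filled, 1) * 2, cfg.n_features))
        d = np.linalg.norm(draw[:, None, :] - concepts[None, :, :], axis=2)
        ok = draw[np.all(d >= cfg.background_exclusion, axis=1)]
        take = min(len(ok), n - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
        if filled == n:
            return out
    raise RuntimeError(
        "background rejection sampling failed; background_exclusion too large"
    )


def simulate_bags(config: SimConfig) -> tuple[list[Bag], SimTruth]:
    """Generate labeled bags with planted concepts; deterministic per seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    concepts = (
        cfg.concept_locations
        if cfg.concept_locations is not None
        else _random_concepts(rng, cfg)
    )
    truth = SimTruth(concepts=np.array(concepts, dtype=float), seed=cfg.seed)
    bags: list[Bag] = []
    lo, hi = cfg.instances_per_bag
    sig_lo, sig_hi = cfg.signal_per_positive
    total = cfg.n_pos + cfg.n_neg
    width = len(str(total))
    for i in range(total):
        positive = i < cfg.n_pos
        sample_id = f"sim{i + 1:0{width}d}"
        n = int(rng.integers(lo, hi + 1))
        if positive:
            n_sig = min(n, int(rng.integers(sig_lo, sig_hi + 1)))
        else:
            n_sig = 0
        n_bg = n - n_sig
        background = _background(rng, n_bg, truth.concepts, cfg)
        concept_idx = np.full(n, -1, dtype=int)
        if n_sig:
            # one driving concept per positive sample: all of a bag's signal
            # segments come from the same planted cluster
            which = np.full(n_sig, int(rng.integers(0, cfg.k_true)))
            signal = np.clip(
                truth.concepts[which]
                + rng.normal(0.0, cfg.concept_spread, size=(n_sig, cfg.n_features)),
                0.0, 1.0,
            )
            instances = np.vstack([signal, background])
            concept_idx[:n_sig] = which
        else:
            instances = background
        label = 1 if positive else -1
        truth.labels_pre_noise[sample_id] = label
        truth.signal_flags[sample_id] = (concept_idx >= 0)
        truth.concept_of[sample_id] = concept_idx
        bags.append(Bag(sample_id, instances, label))
    if cfg.label_noise > 0:
        n_flip = int(round(cfg.label_noise * total))
        flip = rng.choice(total, size=n_flip, replace=False)
        for i in flip:
            bags[i] = Bag(bags[i].sample_id, bags[i].instances, -bags[i].label)
    return bags, truth


def _denormalize(values: np.ndarray, feature_names: Sequence[str]) -> np.ndarray:
    raw = np.empty_like(values)
    for j, name in enumerate(feature_names):
        lo, hi = RAW_RANGES[name]
        raw[:, j] = lo + values[:, j] * (hi - lo)
        if name in _INT_RAW:
            raw[:, j] = np.round(raw[:, j])
    return raw


def raw_bounds(feature_names: Sequence[str] = DEFAULT_FEATURES) -> NormalizationBounds:
    """The de-normalisation bounds used by :func:`bags_to_cncf`."""
    lo = np.array([RAW_RANGES[n][0] for n in feature_names])
    hi = np.array([RAW_RANGES[n][1] for n in feature_names])
    return NormalizationBounds(lo, hi)


def bags_to_cncf(
    bags: Sequence[Bag],
    truth: SimTruth,
    out_dir,
) -> dict:
    """Write one cncf TSV per bag plus ``labels.tsv`` and ``truth.json``.

    Normalised feature values are mapped affinely onto the plausible raw
    ranges of :data:`RAW_RANGES`; non-feature columns are filled
    deterministically from the truth seed so outputs are byte-stable.
    Re-reading the tables and normalising with the stored raw bounds
    recovers the original vectors to within integer-rounding error
    (< 1e-6 in normalised units).
    """
    os.makedirs(out_dir, exist_ok=True)
    feature_names = DEFAULT_FEATURES
    rng = np.random.default_rng(truth.seed + 104729)
    paths = {}
    labels = {}
    for bag in bags:
        raw = _denormalize(bag.instances, feature_names)
        records = []
        for j in range(bag.n_instances):
            row = dict(zip(feature_names, raw[j]))
            nhet = int(row["nhet"])
            records.append(SegmentRecord(
                chrom=int(rng.integers(1, 23)),
                seg=j + 1,
                num_mark=nhet * 2 + 10,
                nhet=nhet,
                cnlr_median=float(row["cnlr_median"]),
                segclust=j + 1,
                cnlr_median_clust=float(row["cnlr_median"]),
                start=int(row["start"]),
                end=int(row["end"]),
                mafR=float(row["mafR"]),
                mafR_clust=float(row["mafR_clust"]),
                cf_em=float(row["cf_em"]),
                tcn_em=float(row["tcn_em"]),
                lcn_em=float(row["lcn_em"]),
            ))
        path = os.path.join(out_dir, f"{bag.sample_id}_cncf.tsv")
        facets_io.write_cncf(records, path)
        paths[bag.sample_id] = path
        if bag.label is not None:
            labels[bag.sample_id] = bag.label
    labels_path = os.path.join(out_dir, "labels.tsv")
    facets_io.write_labels(labels, labels_path)
    bounds = raw_bounds(feature_names)
    truth_path = os.path.join(out_dir, "truth.json")
    with open(truth_path, "w") as fh:
        json.dump({
            "concepts": truth.concepts.tolist(),
            "seed": int(truth.seed),
            "feature_names": list(feature_names),
            "raw_bounds": {
                "minimum": bounds.minimum.tolist(),
                "maximum": bounds.maximum.tolist(),
            },
            "labels_pre_noise": truth.labels_pre_noise,
            "signal_flags": {
                k: np.asarray(v).astype(int).tolist()
                for k, v in truth.signal_flags.items()
            },
        }, fh, indent=2)
        fh.write("\n")
    return {"cncf": paths, "labels": labels_path, "truth": truth_path}
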