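"""The bag abstraction: one tumor sample holding its LOH segment instances.

Only the bag carries an HRD label; individual segments are never labeled.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

POSITIVE = 1
NEGATIVE = -1


@dataclass
class Bag:
    """A sample with its LOH instances as rows of a feature matrix.

    Parameters
    ----------
    sample_id
        Identifier of the sample this bag represents.
    instances
        Array of shape ``(n_instances, n_features)``; at least one row.
    label
        ``+1`` (HRD positive), ``-1`` (HRD negative) or ``None`` when the
        sample is unlabeled (prediction time).
    """

    sample_id: str
    instances: np.ndarray
    label: int | None = None

    def __post_init__(self) -> None:
        inst = np.asarray(self.instances, dtype=float)
        if inst.ndim == 1:
            inst = inst.reshape(1, -1)
        if inst.ndim != 2 or inst.shape[0] < 1:
            raise ValueError(
                f"bag {self.sample_id!r} must contain at least one instance"
            )
        self.instances = inst
        if self.label is not None:
            label = int(self.label)
            if label not in (POSITIVE, NEGATIVE):
                raise ValueError(f"label must be +1 or -1, got {self.label!r}")
            self.label = label

    @property
    def n_instances(self) -> int:
        return self.instances.shape[0]

    @property
    def n_features(self) -> int:
        return self.instances.shape[1]

    def with_features(self, columns) -> "Bag":
        """Return a copy of the bag restricted to the given feature columns."""
        idx = np.asarray(columns, dtype=int)
        return Bag(self.sample_id, self.instances[:, idx], self.label)


def check_dimensions(bags: list[Bag]) -> int:
    """Return the common feature dimension of *bags*, or raise."""
    if not bags:
        raise ValueError("no bags supplied")
    dims = {b.n_features for b in bags}
    if len(dims) != 1:
        raise ValueError(f"bags have inconsistent feature dimensions: {sorted(dims)}")
    return dims.pop()
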