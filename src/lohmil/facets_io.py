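"""Reading, writing and normalising FACETS-dialect segment tables.

A ``*_cncf`` file is a tab-separated table with one row per allele-specific
copy-number segment and 14 columns (chrom, seg, num.mark, nhet, cnlr.median,
segclust, cnlr.median.clust, start, end, mafR, mafR.clust, cf.em, tcn.em,
lcn.em).  Both the dotted headers emitted by FACETS and underscore aliases
are accepted, case-insensitively.

This module turns those tables into per-segment feature vectors (the default
nine-feature view used by the model), min-max normalises them, and groups
them into :class:`~lohmil.bags.Bag` objects.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .bags import Bag

__all__ = [
    "CNCF_COLUMNS",
    "DEFAULT_FEATURES",
    "SegmentRecord",
    "FeatureTable",
    "NormalizationBounds",
    "CncfFormatError",
    "CncfParseError",
    "ConfigurationError",
    "read_cncf",
    "write_cncf",
    "extract_features",
    "fit_minmax",
    "apply_minmax",
    "assemble_bags",
    "read_labels",
    "write_labels",
]

#: The 14 columns of a FACETS cncf table, in canonical file order.
CNCF_COLUMNS = (
    "chrom",
    "seg",
    "num.mark",
    "nhet",
    "cnlr.median",
    "segclust",
    "cnlr.median.clust",
    "start",
    "end",
    "mafR",
    "mafR.clust",
    "cf.em",
    "tcn.em",
    "lcn.em",
)

#: Default nine-feature view of a segment (canonical field names).
DEFAULT_FEATURES = (
    "nhet",
    "cnlr_median",
    "mafR",
    "mafR_clust",
    "start",
    "end",
    "cf_em",
    "tcn_em",
    "lcn_em",
)

_NA_STRINGS = {"", "na", "nan", "n/a", "null", "."}


class CncfFormatError(ValueError):
    """The file does not look like a cncf table (e.g. a column is missing)."""


class CncfParseError(ValueError):
    """A cell could not be parsed as a number."""


class ConfigurationError(ValueError):
    """A requested feature name does not exist."""


def _canon(name: str) -> str:
    return name.strip().lower().replace(".", "_")


#: SegmentRecord attribute names, in Table order (mixed case preserved).
_FIELD_NAMES = (
    "chrom", "seg", "num_mark", "nhet", "cnlr_median", "segclust",
    "cnlr_median_clust", "start", "end", "mafR", "mafR_clust",
    "cf_em", "tcn_em", "lcn_em",
)
_FIELD_BY_CANON = {_canon(n): n for n in _FIELD_NAMES}


@dataclass
class SegmentRecord:
    """One FACETS copy-number/LOH segment (one cncf row).

    All numeric fields may be ``None`` when the file holds an NA marker;
    chromosome X is encoded as 23 and Y as 24.
    """

    chrom: int | None = None
    seg: int | None = None
    num_mark: int | None = None
    nhet: int | None = None
    cnlr_median: float | None = None
    segclust: int | None = None
    cnlr_median_clust: float | None = None
    start: int | None = None
    end: int | None = None
    mafR: float | None = None
    mafR_clust: float | None = None
    cf_em: float | None = None
    tcn_em: float | None = None
    lcn_em: float | None = None

    FIELDS = _FIELD_NAMES

    def get(self, field: str):
        key = _canon(field)
        if key not in _FIELD_BY_CANON:
            raise ConfigurationError(f"unknown segment field {field!r}")
        return getattr(self, _FIELD_BY_CANON[key])


@dataclass
class FeatureTable:
    """Feature vectors extracted from segment records.

    ``values`` has one row per record in the requested feature order;
    ``imputed`` flags rows where at least one missing cell was filled.
    """

    values: np.ndarray
    imputed: np.ndarray
    feature_names: tuple

    @property
    def n_imputed(self) -> int:
        return int(self.imputed.sum())


@dataclass
class NormalizationBounds:
    """Per-feature minimum and maximum observed on a training set."""

    minimum: np.ndarray
    maximum: np.ndarray

    def __post_init__(self) -> None:
        self.minimum = np.asarray(self.minimum, dtype=float)
        self.maximum = np.asarray(self.maximum, dtype=float)
        if self.minimum.shape != self.maximum.shape or self.minimum.ndim != 1:
            raise ValueError("bounds must be 1-D arrays of equal length")
        if np.any(self.minimum > self.maximum):
            raise ValueError("per-feature minimum exceeds maximum")

    @property
    def n_features(self) -> int:
        return self.minimum.shape[0]

    @classmethod
    def unit(cls, n_features: int) -> "NormalizationBounds":
        return cls(np.zeros(n_features), np.ones(n_features))


def _parse_chrom(value: str, row: int):
    v = value.strip()
    if v.lower() in _NA_STRINGS:
        return None
    if v.lower().startswith("chr"):
        v = v[3:]
    if v.upper() == "X":
        return 23
    if v.upper() == "Y":
        return 24
    try:
        return int(float(v))
    except ValueError:
        raise CncfParseError(
            f"row {row}, column 'chrom': cannot parse {value!r}"
        ) from None


def _parse_number(value: str, column: str, row: int, integer: bool):
    v = value.strip()
    if v.lower() in _NA_STRINGS:
        return None
    try:
        x = float(v)
    except ValueError:
        raise CncfParseError(
            f"row {row}, column {column!r}: cannot parse {value!r}"
        ) from None
    if integer:
        return int(round(x))
    return x


_INT_FIELDS = {"seg", "num_mark", "nhet", "segclust", "start", "end"}


def read_cncf(path, sample_id: str | None = None) -> list[SegmentRecord]:
    """Read a FACETS cncf TSV into a list of :class:`SegmentRecord`.

    Missing numeric cells (empty, ``NA``, ``.``) become ``None``.  Raises
    :class:`CncfFormatError` when a mandatory column is absent and
    :class:`CncfParseError` (with the 1-based file row) on non-numeric cells.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment="#")
    colmap = {_canon(c): c for c in df.columns}
    missing = [c for c in CNCF_COLUMNS if _canon(c) not in colmap]
    if missing:
        raise CncfFormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    records: list[SegmentRecord] = []
    for pos in range(len(df)):
        row_no = pos + 2  # 1-based file row, after the header
        kwargs = {}
        for col in CNCF_COLUMNS:
            canon = _canon(col)
            field = _FIELD_BY_CANON[canon]
            raw = df.iloc[pos][colmap[canon]]
            if field == "chrom":
                kwargs[field] = _parse_chrom(str(raw), row_no)
            else:
                kwargs[field] = _parse_number(
                    str(raw), col, row_no, integer=field in _INT_FIELDS
                )
        records.append(SegmentRecord(**kwargs))
    return records


def write_cncf(records: Iterable[SegmentRecord], path) -> None:
    """Write records as a 14-column cncf TSV with dotted FACETS headers."""
    rows = []
    for rec in records:
        row = []
        for col in CNCF_COLUMNS:
            value = rec.get(col)
            if value is None:
                row.append("NA")
            elif _canon(col) in _INT_FIELDS or _canon(col) == "chrom":
                row.append(str(int(value)))
            else:
                row.append(repr(float(value)))
        rows.append(row)
    with open(path, "w") as fh:
        fh.write("\t".join(CNCF_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")


def extract_features(
    records: Sequence[SegmentRecord],
    feature_names: Sequence[str] = DEFAULT_FEATURES,
    fill_value: float = 0.0,
) -> FeatureTable:
    """Project records onto the requested features, imputing missing cells.

    A record with a missing value in any requested feature gets that entry
    filled with ``fill_value`` (default 0) and its ``imputed`` flag set.
    Unknown feature names raise :class:`ConfigurationError`.
    """
    names = []
    for name in feature_names:
        canon = _canon(name)
        if canon not in _FIELD_BY_CANON:
            raise ConfigurationError(f"unknown feature name {name!r}")
        names.append(_FIELD_BY_CANON[canon])
    names = tuple(names)
    n, m = len(records), len(names)
    values = np.empty((n, m), dtype=float)
    imputed = np.zeros(n, dtype=bool)
    for i, rec in enumerate(records):
        for j, name in enumerate(names):
            v = getattr(rec, name)
            if v is None:
                values[i, j] = fill_value
                imputed[i] = True
            else:
                values[i, j] = float(v)
    return FeatureTable(values=values, imputed=imputed, feature_names=names)


def _as_matrix(vectors) -> np.ndarray:
    if isinstance(vectors, FeatureTable):
        vectors = vectors.values
    x = np.asarray(vectors, dtype=float)
    if x.ndim == 1:
        x = x.reshape(1, -1)
    if x.ndim != 2:
        raise ValueError("expected a 2-D array of feature vectors")
    return x


def fit_minmax(vectors) -> NormalizationBounds:
    """Per-feature min/max over all vectors (training-set bounds)."""
    x = _as_matrix(vectors)
    if x.shape[0] == 0:
        raise ValueError("cannot fit normalization bounds on an empty set")
    return NormalizationBounds(x.min(axis=0), x.max(axis=0))


def apply_minmax(vectors, bounds: NormalizationBounds) -> np.ndarray:
    """Map each value to ``(x - min) / (max - min)``, clipped to [0, 1].

    Constant features (min == max) map to 0.
    """
    x = _as_matrix(vectors)
    if x.shape[1] != bounds.n_features:
        raise ValueError(
            f"dimension mismatch: vectors have {x.shape[1]} features, "
            f"bounds have {bounds.n_features}"
        )
    span = bounds.maximum - bounds.minimum
    safe = np.where(span > 0, span, 1.0)
    out = (x - bounds.minimum) / safe
    out[:, span == 0] = 0.0
    return np.clip(out, 0.0, 1.0)


def assemble_bags(
    per_sample_vectors: Mapping[str, np.ndarray],
    labels: Mapping[str, int] | None = None,
) -> list[Bag]:
    """Build one bag per sample, attaching labels where provided.

    Every labeled sample id must appear in the vector mapping, and every
    sample must contribute at least one instance.
    """
    if labels is not None:
        unknown = set(labels) - set(per_sample_vectors)
        if unknown:
            raise ValueError(
                f"labeled sample(s) missing from data: {sorted(unknown)}"
            )
    bags = []
    for sample_id, vectors in per_sample_vectors.items():
        x = _as_matrix(vectors)
        if x.shape[0] == 0:
            raise ValueError(f"sample {sample_id!r} has zero segments")
        label = labels.get(sample_id) if labels is not None else None
        bags.append(Bag(str(sample_id), x, label))
    return bags


_LABEL_ALIASES = {
    "1": 1, "+1": 1, "pos": 1, "positive": 1,
    "-1": -1, "neg": -1, "negative": -1,
}


def read_labels(path) -> dict[str, int]:
    """Read a two-column ``sample_id<TAB>label`` TSV (labels 1/-1 or pos/neg)."""
    labels: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise CncfFormatError(
                    f"{path}: line {lineno}: expected 2 tab-separated columns"
                )
            sample_id, raw = parts[0].strip(), parts[1].strip().lower()
            if lineno == 1 and raw in {"label", "hrd", "status"}:
                continue  # header row
            if raw not in _LABEL_ALIASES:
                raise CncfFormatError(
                    f"{path}: line {lineno}: unrecognised label {parts[1]!r}"
                )
            labels[sample_id] = _LABEL_ALIASES[raw]
    return labels


def write_labels(labels: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for sample_id, label in labels.items():
            fh.write(f"{sample_id}\t{int(label)}\n")
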