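"""Heterogeneous Euclidean-Overlap Metric (HEOM) for mixed-type records.

HEOM combines, per attribute *a*, an overlap distance for nominal attributes
(0 if equal, 1 otherwise) with a range-normalised absolute difference for
numeric attributes, ``|x_a - y_a| / (max_a - min_a)``; a missing value on
either side contributes 1.  The overall distance is the Euclidean norm of the
per-attribute terms, so complete vectors whose numeric values stay inside the
declared ranges satisfy ``0 <= HEOM <= sqrt(p)`` for *p* attributes.

The module also builds inter-cluster distance matrices, either between
per-cluster representatives (numeric mean / nominal mode) or as the mean
pairwise member distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError

NUMERIC = "numeric"
NOMINAL = "nominal"

__all__ = [
    "HeomSchema",
    "DistanceMatrix",
    "heom",
    "cluster_representative",
    "distance_matrix",
]


@dataclass(frozen=True)
class HeomSchema:
    """Attribute schema shared by all vectors entering a HEOM computation.

    Parameters
    ----------
    attributes
        Ordered attribute names.
    kinds
        Parallel sequence of ``"numeric"`` / ``"nominal"`` tags.
    ranges
        ``{attribute: (min, max)}`` observed ranges for numeric attributes,
        normally computed over the *full* dataset, not per cluster.
    """

    attributes: tuple
    kinds: tuple
    ranges: Mapping = field(default_factory=dict)

    def __post_init__(self):
        if len(self.attributes) != len(self.kinds):
            raise ConfigurationError("attributes and kinds must align")
        for a, k in zip(self.attributes, self.kinds):
            if k not in (NUMERIC, NOMINAL):
                raise ConfigurationError(f"unknown attribute kind {k!r} for {a!r}")
            if k == NUMERIC:
                lo, hi = self.ranges.get(a, (np.nan, np.nan))
                if not (np.isnan(lo) or hi >= lo):
                    raise ConfigurationError(f"range for {a!r} has max < min")

    @property
    def numeric(self):
        return tuple(a for a, k in zip(self.attributes, self.kinds) if k == NUMERIC)

    @property
    def nominal(self):
        return tuple(a for a, k in zip(self.attributes, self.kinds) if k == NOMINAL)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, numeric: Sequence[str], nominal: Sequence[str]) -> "HeomSchema":
        """Build a schema whose numeric ranges are observed column-wise on ``df``."""
        attrs = tuple(numeric) + tuple(nominal)
        kinds = (NUMERIC,) * len(numeric) + (NOMINAL,) * len(nominal)
        ranges = {}
        for a in numeric:
            col = pd.to_numeric(df[a], errors="coerce")
            ranges[a] = (float(col.min()), float(col.max()))
        return cls(attrs, kinds, ranges)


def _is_missing(v) -> bool:
    if v is None:
        return True
    try:
        return bool(pd.isna(v))
    except (TypeError, ValueError):
        return False


def heom(x: Mapping, y: Mapping, schema: HeomSchema) -> float:
    """HEOM distance between two records under a shared schema.

    ``x`` and ``y`` are mappings (dict, pandas Series) from attribute name to
    value.  Raises :class:`ValidationError` if an attribute is absent.
    """
    total = 0.0
    for a, kind in zip(schema.attributes, schema.kinds):
        if a not in x or a not in y:
            raise ValidationError(f"attribute {a!r} missing from input record")
        xv, yv = x[a], y[a]
        if _is_missing(xv) or _is_missing(yv):
            d = 1.0
        elif kind == NOMINAL:
            d = 0.0 if xv == yv else 1.0
        else:
            lo, hi = schema.ranges[a]
            rng = hi - lo
            d = 0.0 if rng == 0 else abs(float(xv) - float(yv)) / rng
        total += d * d
    return float(np.sqrt(total))


def cluster_representative(members: pd.DataFrame, schema: HeomSchema) -> pd.Series:
    """Collapse a member table to one mixed vector: numeric mean, nominal mode.

    Missing values are ignored; an all-missing attribute stays missing.  Mode
    ties break toward the lexicographically smallest category label.
    """
    if len(members) == 0:
        raise ValidationError("cannot form a representative of an empty cluster")
    rep = {}
    for a, kind in zip(schema.attributes, schema.kinds):
        col = members[a]
        if kind == NUMERIC:
            val = pd.to_numeric(col, errors="coerce").mean()
            rep[a] = float(val) if pd.notna(val) else np.nan
        else:
            counts = col.dropna().astype(str).value_counts()
            if counts.empty:
                rep[a] = np.nan
            else:
                best = counts.max()
                rep[a] = sorted(counts.index[counts == best])[0]
    return pd.Series(rep, index=list(schema.attributes))


def _pairwise_heom(A: pd.DataFrame, B: pd.DataFrame, schema: HeomSchema) -> np.ndarray:
    """Dense |A| x |B| HEOM matrix, vectorised per attribute."""
    out = np.zeros((len(A), len(B)))
    for a, kind in zip(schema.attributes, schema.kinds):
        if kind == NUMERIC:
            xa = pd.to_numeric(A[a], errors="coerce").to_numpy(float)
            xb = pd.to_numeric(B[a], errors="coerce").to_numpy(float)
            lo, hi = schema.ranges[a]
            rng = hi - lo
            if rng == 0:
                d = np.zeros((len(A), len(B)))
            else:
                d = np.abs(xa[:, None] - xb[None, :]) / rng
            miss = np.isnan(xa)[:, None] | np.isnan(xb)[None, :]
            d = np.where(miss, 1.0, d)
        else:
            xa = A[a].to_numpy(object)
            xb = B[a].to_numpy(object)
            ma = np.array([_is_missing(v) for v in xa])
            mb = np.array([_is_missing(v) for v in xb])
            d = (xa[:, None] != xb[None, :]).astype(float)
            d = np.where(ma[:, None] | mb[None, :], 1.0, d)
        out += d * d
    return np.sqrt(out)


def _elementwise_heom(A: pd.DataFrame, B: pd.DataFrame, schema: HeomSchema) -> np.ndarray:
    """Row-aligned HEOM distances (A_i vs B_i), vectorised per attribute."""
    out = np.zeros(len(A))
    for a, kind in zip(schema.attributes, schema.kinds):
        if kind == NUMERIC:
            xa = pd.to_numeric(A[a], errors="coerce").to_numpy(float)
            xb = pd.to_numeric(B[a], errors="coerce").to_numpy(float)
            lo, hi = schema.ranges[a]
            rng = hi - lo
            d = np.zeros(len(A)) if rng == 0 else np.abs(xa - xb) / rng
            d = np.where(np.isnan(xa) | np.isnan(xb), 1.0, d)
        else:
            xa = A[a].to_numpy(object)
            xb = B[a].to_numpy(object)
            ma = np.array([_is_missing(v) for v in xa])
            mb = np.array([_is_missing(v) for v in xb])
            d = np.where(ma | mb, 1.0, (xa != xb).astype(float))
        out += d * d
    return np.sqrt(out)


@dataclass
class DistanceMatrix:
    """Symmetric, zero-diagonal HEOM distances among labelled leaf clusters."""

    labels: list
    values: np.ndarray
    mode: str

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ConfigurationError("distance matrix shape does not match labels")
        self.values = v


def distance_matrix(
    leaf_clusters: Mapping[str, pd.DataFrame],
    schema: HeomSchema,
    mode: str = "representative",
    pair_sample_limit: int | None = None,
    seed: int = 0,
) -> DistanceMatrix:
    """HEOM distance matrix among leaf clusters.

    mode="representative" measures between per-cluster representatives;
    mode="average" is the mean pairwise member distance, uniformly subsampled
    (fixed ``seed``) when a pair of clusters exceeds ``pair_sample_limit``
    member pairs.  The diagonal is zero by construction in both modes.
    """
    if len(leaf_clusters) < 2:
        raise ValidationError("need at least two leaf clusters")
    if mode not in ("representative", "average"):
        raise ConfigurationError(f"unknown mode {mode!r}")
    labels = list(leaf_clusters)
    m = len(labels)
    values = np.zeros((m, m))
    rng = np.random.default_rng(seed)
    if mode == "representative":
        reps = {lab: cluster_representative(df, schema) for lab, df in leaf_clusters.items()}
        for i in range(m):
            for j in range(i + 1, m):
                d = heom(reps[labels[i]], reps[labels[j]], schema)
                values[i, j] = values[j, i] = d
    else:
        for i in range(m):
            for j in range(i + 1, m):
                A = leaf_clusters[labels[i]]
                B = leaf_clusters[labels[j]]
                n_pairs = len(A) * len(B)
                if pair_sample_limit is not None and n_pairs > pair_sample_limit:
                    ia = rng.integers(0, len(A), size=pair_sample_limit)
                    ib = rng.integers(0, len(B), size=pair_sample_limit)
                    d = float(
                        _elementwise_heom(
                            A.iloc[ia].reset_index(drop=True),
                            B.iloc[ib].reset_index(drop=True),
                            schema,
                        ).mean()
                    )
                else:
                    d = float(_pairwise_heom(A, B, schema).mean())
                values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=labels, values=values, mode=mode)
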