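"""Level-1 taxonomy: k-means over standardised climate vectors.

The clustering unit is the school-year climate vector.  Candidate cluster
counts are compared with a spherical shared-variance Gaussian-mixture BIC
(smaller is better) and the mean silhouette; cluster centroids are profiled
on the native scale together with Z-scores
``(centroid - overall mean) / overall sd`` that place each cluster on a
good-to-poor climate spectrum.  Injury cases inherit the cluster of their
matched school-year vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import kmeans_plusplus
from sklearn.metrics import silhouette_score

from .exceptions import ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "Standardization",
    "KMeansModel",
    "KSelectionCurve",
    "ClusterProfile",
    "standardize",
    "fit_kmeans",
    "kmeans_bic",
    "silhouette",
    "scan_k",
    "zscore_profile",
    "profile_clusters",
    "assign_cases",
]

_MAX_RESEEDS = 50


@dataclass
class Standardization:
    """Column-wise z-scoring parameters; invertible exactly."""

    means: pd.Series
    sds: pd.Series

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return (X - self.means) / self.sds

    def inverse(self, Z) -> pd.DataFrame:
        Z = pd.DataFrame(Z, columns=self.means.index)
        return Z * self.sds + self.means


def standardize(X: pd.DataFrame):
    """Z-score each column (sample sd).  Returns (Z, Standardization)."""
    X = X.apply(pd.to_numeric, errors="coerce")
    means = X.mean()
    sds = X.std(ddof=1)
    zero = sds.index[(sds == 0) | sds.isna()].tolist()
    if zero:
        raise ValidationError(f"zero-variance column(s): {zero}")
    st = Standardization(means=means, sds=sds)
    return st.transform(X), st


@dataclass
class KMeansModel:
    k: int
    centroids: np.ndarray          # k x p, in the space the model was fitted on
    labels: np.ndarray             # length n, values 0..k-1
    sse: float                     # total within-cluster sum of squared distances
    seed: int
    n_init: int
    n_reseeds: int = 0             # empty-cluster restarts across all inits
    n_iter: int = 0                # Lloyd iterations of the winning run


def _lloyd(X: np.ndarray, centers: np.ndarray, max_iter: int, tol: float):
    """Lloyd iterations from given centers.

    Returns (centers, labels, sse, n_iter) or None on empty-cluster collapse.
    SSE is asserted non-increasing across iterations.
    """
    n, _ = X.shape
    k = centers.shape[0]
    prev_sse = np.inf
    for it in range(1, max_iter + 1):
        d2 = cdist(X, centers, "sqeuclidean")
        labels = d2.argmin(axis=1)  # argmin ties -> lowest cluster index
        sse = float(d2[np.arange(n), labels].sum())
        if not sse <= prev_sse * (1 + 1e-12) + 1e-12:
            raise AssertionError("k-means SSE increased across a Lloyd iteration")
        counts = np.bincount(labels, minlength=k)
        if (counts == 0).any():
            return None
        centers = np.vstack(
            [X[labels == j].mean(axis=0) for j in range(k)]
        )
        if prev_sse - sse <= tol * max(sse, np.finfo(float).tiny):
            break
        prev_sse = sse
    # final consistent assignment against the last (mean-updated) centers
    d2 = cdist(X, centers, "sqeuclidean")
    labels = d2.argmin(axis=1)
    sse = float(d2[np.arange(n), labels].sum())
    if (np.bincount(labels, minlength=k) == 0).any():
        return None
    return centers, labels, sse, it


def fit_kmeans(
    X,
    k: int,
    seed: int = 0,
    n_init: int = 25,
    max_iter: int = 300,
    tol: float = 1e-8,
) -> KMeansModel:
    """Best-of-``n_init`` Lloyd k-means with k-means++ seeding.

    Each run iterates until the relative SSE improvement drops below ``tol``
    or ``max_iter`` iterations; the run with the lowest SSE wins.  A run that
    collapses to an empty cluster is re-seeded (counted in ``n_reseeds``).
    Deterministic for a fixed ``seed``.
    """
    Xa = np.asarray(X, dtype=float)
    n = Xa.shape[0]
    if n < k:
        raise ValidationError(f"need at least k={k} rows, got {n}")
    if k < 1:
        raise ValidationError("k must be >= 1")
    rng = np.random.default_rng(seed)
    best = None
    n_reseeds = 0
    runs = 0
    while runs < n_init:
        init_seed = int(rng.integers(0, 2**31 - 1))
        centers, _ = kmeans_plusplus(Xa, n_clusters=k, random_state=init_seed)
        res = _lloyd(Xa, centers, max_iter, tol)
        if res is None:
            n_reseeds += 1
            if n_reseeds > _MAX_RESEEDS:
                raise ValidationError(
                    "k-means kept collapsing to empty clusters; too few distinct rows?"
                )
            continue
        runs += 1
        if best is None or res[2] < best[2]:
            best = res
    centers, labels, sse, n_iter = best
    if n_reseeds:
        log.debug("k-means k=%d: %d empty-cluster re-seeds", k, n_reseeds)
    return KMeansModel(
        k=k,
        centroids=centers,
        labels=labels,
        sse=sse,
        seed=seed,
        n_init=n_init,
        n_reseeds=n_reseeds,
        n_iter=n_iter,
    )


def kmeans_bic(model: KMeansModel, X) -> float:
    """Schwarz BIC of a fitted k-means model under the spherical
    shared-variance Gaussian-mixture view (smaller is better).

    With ``sigma2 = SSE / (d * (n - k))``, mixing proportions ``n_j / n`` and
    ``p = k*d + k`` free parameters,

    ``lnL = sum_j n_j*ln(n_j/n) - (n*d/2)*ln(2*pi*sigma2) - d*(n-k)/2``
    ``BIC = -2*lnL + p*ln(n)``
    """
    Xa = np.asarray(X, dtype=float)
    n, d = Xa.shape
    k = model.k
    if n <= k:
        raise ValidationError("BIC undefined for n <= k")
    nj = np.bincount(model.labels, minlength=k).astype(float)
    sigma2 = model.sse / (d * (n - k))
    sigma2 = max(sigma2, np.finfo(float).tiny)  # guard degenerate perfect fits
    lnl = (
        float(np.sum(nj * np.log(nj / n)))
        - 0.5 * n * d * np.log(2 * np.pi * sigma2)
        - 0.5 * d * (n - k)
    )
    p = k * d + k
    return float(-2.0 * lnl + p * np.log(n))


def silhouette(model: KMeansModel, X) -> float:
    """Mean silhouette over units (Euclidean); singleton-cluster units score 0."""
    if model.k < 2:
        raise ValidationError("silhouette requires k >= 2")
    return float(silhouette_score(np.asarray(X, float), model.labels, metric="euclidean"))


@dataclass
class KSelectionCurve:
    table: pd.DataFrame  # columns: k, bic, silhouette, sse
    chosen_k: int
    rationale: str
    models: dict = field(default_factory=dict, repr=False)

    @property
    def bic_argmin(self) -> int:
        return int(self.table.loc[self.table["bic"].idxmin(), "k"])


def scan_k(
    X,
    k_range=range(2, 9),
    seed: int = 0,
    chosen_k: int = 5,
    n_init: int = 25,
) -> KSelectionCurve:
    """Fit k-means for every k in ``k_range``; record BIC, silhouette, SSE.

    ``chosen_k`` is a configuration input (cluster-count choice ultimately
    rests on interpretability, which is not automated); the BIC minimum over
    the scan is exposed as an advisory ``bic_argmin`` only.
    """
    ks = sorted(set(int(k) for k in k_range))
    if not ks or ks[0] < 2:
        raise ValidationError("k_range must contain integers >= 2")
    rows, models = [], {}
    for k in ks:
        model = fit_kmeans(X, k, seed=seed, n_init=n_init)
        rows.append(
            {
                "k": k,
                "bic": kmeans_bic(model, X),
                "silhouette": silhouette(model, X),
                "sse": model.sse,
            }
        )
        models[k] = model
    table = pd.DataFrame(rows)
    if chosen_k not in ks:
        raise ValidationError(f"chosen_k={chosen_k} outside scanned range {ks}")
    rationale = (
        f"chosen_k={chosen_k} set by configuration (interpretability); "
        f"BIC minimum over scan at k={int(table.loc[table['bic'].idxmin(), 'k'])}"
    )
    return KSelectionCurve(table=table, chosen_k=chosen_k, rationale=rationale, models=models)


def zscore_profile(
    centroids: pd.DataFrame, overall_mean: pd.Series, overall_sd: pd.Series
) -> pd.DataFrame:
    """Z-score of each native-scale centroid against the overall mean/sd."""
    return (centroids - overall_mean) / overall_sd


@dataclass
class ClusterProfile:
    """Native-scale cluster profile with Z-scores, Table-style."""

    overall_mean: pd.Series
    overall_sd: pd.Series
    centroids_native: pd.DataFrame  # cluster x variable
    zscores: pd.DataFrame           # cluster x variable, unrounded
    counts: pd.Series               # units (or cases) per cluster

    def to_frame(self) -> pd.DataFrame:
        """Variable x cluster grid: centroid with the 2-dp Z in parentheses."""
        out = pd.DataFrame(index=self.centroids_native.columns)
        out["overall"] = [
            f"{self.overall_mean[v]:.3f} ({self.overall_sd[v]:.3f})"
            for v in out.index
        ]
        for c in self.centroids_native.index:
            out[str(c)] = [
                f"{self.centroids_native.loc[c, v]:.3f} (Z={self.zscores.loc[c, v]:+.2f})"
                for v in out.index
            ]
        out.index.name = "variable"
        return out


def profile_clusters(native: pd.DataFrame, labels) -> ClusterProfile:
    """Profile clusters on the native variable scales.

    ``native`` holds one row per unit (school-year, or matched case when a
    case-weighted profile is wanted) and ``labels`` the unit's cluster.  The
    per-cluster centroid is the mean of its member rows; Z-scores compare it
    to the overall mean/sd of the same rows, so the count-weighted mean of
    Z-scores is ~0 per variable.
    """
    native = native.apply(pd.to_numeric, errors="coerce")
    labels = pd.Series(np.asarray(labels), index=native.index, name="cluster")
    overall_mean = native.mean()
    overall_sd = native.std(ddof=1)
    cent = native.groupby(labels).mean()
    z = zscore_profile(cent, overall_mean, overall_sd)
    counts = labels.value_counts().sort_index()
    return ClusterProfile(
        overall_mean=overall_mean,
        overall_sd=overall_sd,
        centroids_native=cent,
        zscores=z,
        counts=counts,
    )


def assign_cases(
    school_year_labels: pd.Series, integrated: pd.DataFrame
) -> pd.Series:
    """Propagate school-year cluster labels to injury cases.

    ``school_year_labels`` is indexed by ``(school_id, year)``; each matched
    case inherits the label of its ``(school_id, climate_source_year)`` pair.
    Unmatched cases are omitted.  Returns a Series indexed by case_id.
    """
    matched = integrated[integrated["match_status"] != "unmatched"]
    keys = list(zip(matched["school_id"], matched["climate_source_year"].astype(int)))
    mapped = school_year_labels.reindex(keys)
    if mapped.isna().any():
        missing = [k for k, v in zip(keys, mapped) if pd.isna(v)]
        raise ValidationError(
            f"{len(missing)} matched cases reference unclustered school-years, e.g. {missing[:3]}"
        )
    return pd.Series(
        mapped.to_numpy(),
        index=pd.Index(matched["case_id"].to_numpy(), name="case_id"),
        name="cluster",
    )
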