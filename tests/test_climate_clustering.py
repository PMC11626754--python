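"""Level-1 machinery: standardisation, Lloyd k-means vs exhaustive search,
BIC formula oracle, silhouette oracle, k-scan, Z-score profiling."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import KMeans

from climtax import (
    ValidationError,
    assign_cases,
    fit_kmeans,
    kmeans_bic,
    profile_clusters,
    scan_k,
    silhouette,
    standardize,
    zscore_profile,
)
from climtax.climate import KMeansModel


# ---------------------------------------------------------------- oracles
def brute_force_sse(X, k):
    """Minimum within-cluster SSE over all k-partitions (exhaustive)."""
    n = len(X)
    best = np.inf
    for assignment in itertools.product(range(k), repeat=n):
        if len(set(assignment)) < k:
            continue
        sse = 0.0
        lab = np.array(assignment)
        for j in range(k):
            members = X[lab == j]
            sse += ((members - members.mean(axis=0)) ** 2).sum()
        best = min(best, sse)
    return best


def bic_oracle(sse, nj, n, d, k):
    """Term-by-term evaluation of the spherical shared-variance BIC."""
    sigma2 = sse / (d * (n - k))
    lnl = (
        sum(v * math.log(v / n) for v in nj)
        - 0.5 * n * d * math.log(2 * math.pi * sigma2)
        - 0.5 * d * (n - k)
    )
    return -2 * lnl + (k * d + k) * math.log(n)


def silhouette_oracle(X, labels):
    n = len(X)
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    vals = []
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            vals.append(0.0)
            continue
        a = np.mean([D[i, j] for j in same])
        b = min(
            np.mean([D[i, j] for j in range(n) if labels[j] == other])
            for other in set(labels) - {labels[i]}
        )
        vals.append(0.0 if max(a, b) == 0 else (b - a) / max(a, b))
    return float(np.mean(vals))


# ---------------------------------------------------------- standardize
class TestStandardize:
    def test_two_point_column(self):
        Z, st = standardize(pd.DataFrame({"x": [0.0, 10.0]}))
        np.testing.assert_allclose(Z["x"], [-math.sqrt(0.5), math.sqrt(0.5)])

    def test_round_trip(self, rng):
        X = pd.DataFrame(rng.normal(10, 3, size=(40, 4)), columns=list("abcd"))
        Z, st = standardize(X)
        np.testing.assert_allclose(st.inverse(Z).to_numpy(), X.to_numpy(), atol=1e-12)

    def test_identical_columns_standardize_identically(self, rng):
        x = rng.normal(size=30)
        Z, _ = standardize(pd.DataFrame({"a": x, "b": x.copy()}))
        np.testing.assert_allclose(Z["a"], Z["b"])

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError, match="flat"):
            standardize(pd.DataFrame({"ok": [1.0, 2.0], "flat": [3.0, 3.0]}))


# ------------------------------------------------------------- k-means
class TestFitKMeans:
    def test_separated_pairs(self):
        X = np.array([[0, 0], [0, 1], [10, 0], [10, 1]], float)
        m = fit_kmeans(X, 2, seed=0, n_init=5)
        assert m.sse == pytest.approx(1.0)
        assert m.labels[0] == m.labels[1] and m.labels[2] == m.labels[3]
        assert m.labels[0] != m.labels[2]

    def test_matches_bruteforce_partition_optimum_1d(self, rng):
        X = rng.normal(size=(10, 1))
        m = fit_kmeans(X, 2, seed=1, n_init=50)
        assert m.sse == pytest.approx(brute_force_sse(X, 2), rel=1e-9)

    @pytest.mark.parametrize("trial", range(4))
    def test_matches_bruteforce_small_mixed_instances(self, trial, rng):
        n, d, k = 8 + trial, 2, 2 + trial % 2
        X = rng.normal(size=(n, d))
        m = fit_kmeans(X, k, seed=trial, n_init=200)
        assert m.sse == pytest.approx(brute_force_sse(X, k), rel=1e-9)

    def test_k1_closed_form(self, rng):
        X = rng.normal(size=(25, 3))
        m = fit_kmeans(X, 1, seed=0, n_init=1)
        np.testing.assert_allclose(m.centroids[0], X.mean(axis=0), atol=1e-12)
        assert m.sse == pytest.approx(((X - X.mean(0)) ** 2).sum())

    def test_agrees_with_sklearn_reference(self, rng):
        X = rng.normal(size=(200, 4))
        X[:100] += 6
        ours = fit_kmeans(X, 2, seed=0, n_init=10)
        ref = KMeans(n_clusters=2, n_init=10, random_state=0).fit(X)
        assert ours.sse == pytest.approx(ref.inertia_, rel=1e-6)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValidationError):
            fit_kmeans(np.zeros((2, 2)), 3)


class TestBIC:
    def test_formula_oracle_small_instance(self, rng):
        X = rng.normal(size=(6, 1))
        m = fit_kmeans(X, 2, seed=0, n_init=20)
        nj = np.bincount(m.labels)
        assert kmeans_bic(m, X) == pytest.approx(bic_oracle(m.sse, nj, 6, 1, 2), rel=1e-12)

    def test_extra_cluster_penalty_is_d_plus_1_log_n(self):
        # the parameter-count part of the criterion grows by (d+1)*ln(n) per
        # added cluster, independent of the data
        n, d = 50, 6
        pen = lambda k: (k * d + k) * math.log(n)
        assert pen(6) - pen(5) == pytest.approx((d + 1) * math.log(n))

    def test_k1_computable_from_sample_variance(self, rng):
        X = rng.normal(size=(30, 2))
        m = fit_kmeans(X, 1, seed=0, n_init=1)
        assert kmeans_bic(m, X) == pytest.approx(
            bic_oracle(((X - X.mean(0)) ** 2).sum(), [30], 30, 2, 1)
        )

    def test_n_le_k_rejected(self):
        X = np.array([[0.0], [1.0]])
        m = fit_kmeans(X, 2, seed=0, n_init=1)
        with pytest.raises(ValidationError):
            kmeans_bic(m, X)


class TestSilhouette:
    def test_tight_far_blobs(self, rng):
        X = np.vstack([rng.normal(0, 0.05, (20, 2)), rng.normal(8, 0.05, (20, 2))])
        m = fit_kmeans(X, 2, seed=0, n_init=5)
        assert silhouette(m, X) > 0.9

    def test_identical_points_give_zero(self):
        X = np.zeros((6, 2))
        m = KMeansModel(
            k=2, centroids=np.zeros((2, 2)), labels=np.array([0, 0, 0, 1, 1, 1]),
            sse=0.0, seed=0, n_init=1,
        )
        assert silhouette(m, X) == 0.0

    def test_matches_bruteforce_oracle(self, rng):
        X = rng.normal(size=(6, 2))
        m = fit_kmeans(X, 2, seed=3, n_init=20)
        assert silhouette(m, X) == pytest.approx(silhouette_oracle(X, m.labels), rel=1e-9)

    def test_k1_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        m = fit_kmeans(X, 1, seed=0, n_init=1)
        with pytest.raises(ValidationError):
            silhouette(m, X)


class TestScanK:
    def test_single_k_range(self, rng):
        X = rng.normal(size=(30, 2))
        curve = scan_k(X, range(2, 3), seed=0, chosen_k=2, n_init=5)
        assert len(curve.table) == 1 and curve.chosen_k == 2

    def test_entry_per_scanned_k(self, rng):
        X = rng.normal(size=(60, 2))
        X[:30] += 5
        curve = scan_k(X, range(2, 6), seed=0, chosen_k=3, n_init=5)
        assert curve.table["k"].tolist() == [2, 3, 4, 5]
        assert curve.table[["bic", "silhouette", "sse"]].notna().all().all()

    def test_chosen_k_outside_range_rejected(self, rng):
        X = rng.normal(size=(30, 2))
        with pytest.raises(ValidationError):
            scan_k(X, range(2, 4), chosen_k=7)


# ------------------------------------------------------------ profiling
class TestProfiles:
    def test_centroid_at_overall_mean_has_zero_z(self, rng):
        df = pd.DataFrame(rng.normal(size=(40, 2)), columns=["a", "b"])
        labels = np.array([0, 1] * 20)
        prof = profile_clusters(df, labels)
        z = zscore_profile(
            pd.DataFrame([df.mean()], index=[0]), prof.overall_mean, prof.overall_sd
        )
        np.testing.assert_allclose(z.to_numpy(), 0.0, atol=1e-12)

    def test_count_weighted_z_scores_balance(self, small_dataset):
        climate, _, _ = small_dataset
        from climtax.synthetic import CLIMATE_ITEMS

        X = climate[CLIMATE_ITEMS]
        Z, _ = standardize(X)
        m = fit_kmeans(Z, 5, seed=0, n_init=10)
        prof = profile_clusters(X, m.labels)
        w = prof.counts / prof.counts.sum()
        balance = (prof.zscores.mul(w, axis=0)).sum()
        assert np.abs(balance.to_numpy()).max() < 0.02


class TestAssignCases:
    def test_cases_inherit_school_year_cluster_and_conserve(self, small_dataset):
        climate, injuries, _ = small_dataset
        from climtax import integrate
        from climtax.synthetic import CLIMATE_ITEMS

        integ, rep = integrate(climate, injuries)
        Z, _ = standardize(climate[CLIMATE_ITEMS])
        m = fit_kmeans(Z, 5, seed=0, n_init=10)
        sy = pd.Series(
            m.labels, index=pd.MultiIndex.from_frame(climate[["school_id", "year"]])
        )
        cc = assign_cases(sy, integ)
        # conservation
        assert len(cc) == rep.n_same_year + rep.n_fallback
        # two cases sharing a school-year share a cluster
        matched = integ[integ["match_status"] != "unmatched"]
        key = list(zip(matched["school_id"], matched["climate_source_year"]))
        df = pd.DataFrame({"key": key, "cluster": cc.to_numpy()})
        assert (df.groupby("key")["cluster"].nunique() == 1).all()
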