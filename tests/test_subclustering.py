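"""Mixed-data sub-clustering: separable limits, brute-force objective oracle,
cross-tabulation profiles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from climtax import ValidationError, crosstab_profile, fit_subclusters
from climtax.subclusters import DEFAULT_CATEGORICAL_VARS, DEFAULT_NUMERIC_VARS, _prepare


def kprototypes_objective_oracle(Z, C, labels, gamma):
    """Objective of a partition with per-part optimal prototypes
    (numeric mean, categorical mode)."""
    total = 0.0
    for j in set(labels):
        members = labels == j
        if Z.shape[1]:
            mu = Z[members].mean(axis=0)
            total += ((Z[members] - mu) ** 2).sum()
        for v in range(C.shape[1]):
            counts = np.bincount(C[members, v])
            total += gamma * (members.sum() - counts.max())
    return total


def brute_force_best_partition(Z, C, k, gamma):
    n = len(Z)
    best = np.inf
    for assignment in itertools.product(range(k), repeat=n):
        if len(set(assignment)) < k:
            continue
        best = min(best, kprototypes_objective_oracle(Z, C, np.array(assignment), gamma))
    return best


def test_perfect_gender_separation_recovered(mixed_cases):
    # gender exactly co-varies with place/cause/type: the split is clear-cut
    m = fit_subclusters(mixed_cases, k=2, seed=0, n_init=10)
    ari = adjusted_rand_score((mixed_cases["gender"] == "girl").astype(int), m.labels.to_numpy())
    assert ari == 1.0


def test_objective_matches_bruteforce_on_handcrafted_cases(mixed_cases):
    gamma = 3.0
    Z, C, _, _ = _prepare(mixed_cases, DEFAULT_NUMERIC_VARS, DEFAULT_CATEGORICAL_VARS)
    expected = brute_force_best_partition(Z, C, 2, gamma)
    m = fit_subclusters(mixed_cases, k=2, gamma=gamma, seed=1, n_init=50)
    assert m.cost == pytest.approx(expected, rel=1e-9)


@pytest.mark.parametrize("trial", range(3))
def test_objective_matches_bruteforce_on_random_instances(trial, rng):
    n = 8
    cases = pd.DataFrame(
        {
            "case_id": [f"R{i}" for i in range(n)],
            "age_group": rng.integers(6, 13, n),
            "gender": rng.choice(["boy", "girl"], n),
            "event_place": rng.choice(["yard", "classroom", "stairs"], n),
            "event_term": rng.choice(["break", "lesson"], n),
            "anatomic_place": rng.choice(["head", "hand"], n),
            "injury_cause": rng.choice(["game", "slipping"], n),
            "injury_type": rng.choice(["trauma", "superficial_incision"], n),
        }
    )
    gamma = [0.5, 1.0, 3.0][trial]
    Z, C, _, _ = _prepare(cases, DEFAULT_NUMERIC_VARS, DEFAULT_CATEGORICAL_VARS)
    expected = brute_force_best_partition(Z, C, 2, gamma)
    m = fit_subclusters(cases, k=2, gamma=gamma, seed=trial, n_init=100)
    assert m.cost == pytest.approx(expected, rel=1e-9)


def test_k1_prototype_is_means_plus_modes(mixed_cases):
    m = fit_subclusters(mixed_cases, k=1, seed=0, n_init=1)
    assert m.prototypes_numeric.loc[0, "age_group"] == pytest.approx(
        mixed_cases["age_group"].mean()
    )
    assert m.prototypes_categorical.loc[0, "event_place"] in {"classroom", "yard"}
    # tie on place (4 vs 4): lexicographic tie-break picks "classroom"
    assert m.prototypes_categorical.loc[0, "event_place"] == "classroom"


def test_degenerate_inputs_rejected(mixed_cases):
    with pytest.raises(ValidationError):
        fit_subclusters(mixed_cases.head(1), k=2)
    same = pd.concat([mixed_cases.head(1)] * 6).reset_index(drop=True)
    same["case_id"] = [f"D{i}" for i in range(6)]
    with pytest.raises(ValidationError):
        fit_subclusters(same, k=2)


def test_case_count_conservation_and_label_coverage(mixed_cases):
    m = fit_subclusters(mixed_cases, k=2, seed=0, n_init=10)
    assert m.labels.value_counts().sum() == len(mixed_cases)
    assert set(m.labels.index) == set(mixed_cases["case_id"])


def test_onehot_variant_agrees_on_separable_data(mixed_cases):
    m = fit_subclusters(mixed_cases, k=2, seed=0, n_init=10, method="onehot")
    ari = adjusted_rand_score((mixed_cases["gender"] == "girl").astype(int), m.labels.to_numpy())
    assert ari == 1.0


class TestCrosstabProfile:
    @pytest.mark.parametrize(
        "n_sub, n_hit, expected", [(900, 247, 27.4), (387, 287, 74.2)]
    )
    def test_published_style_within_subcluster_percentages(self, n_sub, n_hit, expected):
        n = n_sub + 100
        cases = pd.DataFrame(
            {
                "case_id": [f"C{i}" for i in range(n)],
                "age_group": 9,
                "gender": ["boy"] * n_hit + ["girl"] * (n_sub - n_hit) + ["boy"] * 100,
                "event_place": ["yard"] * n_sub + ["classroom"] * 100,
                "event_term": ["break"] * n_sub + ["lesson"] * 100,
                "anatomic_place": ["head"] * n_sub + ["hand"] * 100,
                "injury_cause": ["game"] * n_sub + ["slipping"] * 100,
                "injury_type": ["trauma"] * n_sub + ["superficial_incision"] * 100,
            }
        )
        m = fit_subclusters(cases, k=2, seed=0, n_init=5)
        prof = crosstab_profile(m, cases)
        # identify the sub-cluster of size n_sub
        sub = prof.n_cases.index[prof.n_cases == n_sub][0]
        assert prof.tables["gender"][sub].table.loc["boy", "percent"] == expected

    def test_empty_category_rendered_as_zero(self, mixed_cases):
        m = fit_subclusters(mixed_cases, k=2, seed=0, n_init=10)
        frame = crosstab_profile(m, mixed_cases).to_frame()
        girls_col_cells = frame.loc[
            (frame["variable"] == "injury_cause") & (frame["category"] == "game")
        ]
        assert any("0 (0.0%)" in str(v) for v in girls_col_cells.iloc[0, 2:].tolist())

    def test_extremities_merge(self, mixed_cases):
        m = fit_subclusters(mixed_cases, k=2, seed=0, n_init=10)
        prof = crosstab_profile(m, mixed_cases, merge_extremities=True)
        cats = {c for ft in prof.tables["anatomic_place"].values() for c in ft.table.index}
        assert "extremities" in cats and "foot" not in cats and "hand" not in cats
        prof2 = crosstab_profile(m, mixed_cases, merge_extremities=False)
        cats2 = {c for ft in prof2.tables["anatomic_place"].values() for c in ft.table.index}
        assert "foot" in cats2 or "hand" in cats2

    def test_subcluster_ns_sum_to_parent_n(self, mixed_cases):
        m = fit_subclusters(mixed_cases, k=2, seed=0, n_init=10)
        prof = crosstab_profile(m, mixed_cases)
        assert prof.n_cases.sum() == len(mixed_cases)
        for var, per_sub in prof.tables.items():
            for s, ft in per_sub.items():
                assert ft.table["count"].sum() == prof.n_cases[s]


def test_planted_gender_dominated_subclasses_recovered(small_dataset):
    """Within one planted climate class, sub-clustering on the true member
    cases recovers the planted sub-classes with ARI >= 0.8."""
    _, injuries, gt = small_dataset
    cls = injuries["case_id"].map(lambda i: gt.case_to_subclass[i][0])
    sub = injuries[cls == 0]
    truth = [gt.case_to_subclass[i][1] for i in sub["case_id"]]
    m = fit_subclusters(sub, k=2, seed=0, n_init=15)
    assert adjusted_rand_score(truth, m.labels.to_numpy()) >= 0.8
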