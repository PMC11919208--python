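import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from idscn import (
    ClinicalTable,
    FeatureMatrix,
    WardSubtyper,
    bh_fdr,
    choose_k,
    contrast_subtypes,
    hierarchical_cluster,
    jaccard_stability,
)


def blobs(rng, sizes, centers, sd=1.0):
    X = np.vstack([
        c + sd * rng.standard_normal((n, len(c)))
        for n, c in zip(sizes, centers)
    ])
    truth = np.concatenate([np.full(n, k) for k, n in enumerate(sizes)])
    return X, truth


def test_two_separated_blobs_recovered_exactly(rng):
    X, truth = blobs(rng, [20, 30], [np.zeros(4), np.full(4, 10.0)])
    labels = hierarchical_cluster(X, 2)
    assert adjusted_rand_score(truth, labels) == 1.0


def test_k_equal_n_gives_singletons(rng):
    X = rng.standard_normal((7, 3))
    labels = hierarchical_cluster(X, 7)
    assert sorted(labels) == list(range(1, 8))


def test_row_permutation_only_relabels(rng):
    X, _ = blobs(rng, [12, 12, 12], [np.zeros(3), np.full(3, 8.0),
                                     np.full(3, -8.0)])
    labels = hierarchical_cluster(X, 3)
    perm = rng.permutation(len(X))
    labels_perm = hierarchical_cluster(X[perm], 3)
    assert adjusted_rand_score(labels[perm], labels_perm) == 1.0


def test_k_larger_than_n_rejected(rng):
    with pytest.raises(ValueError):
        hierarchical_cluster(rng.standard_normal((4, 2)), 5)


def test_choose_k_two_blobs_unanimous(rng):
    X, _ = blobs(rng, [25, 25], [np.zeros(5), np.full(5, 12.0)])
    k, votes = choose_k(X)
    assert k == 2
    assert set(votes.values()) == {2}
    assert len(votes) >= 5


def test_choose_k_three_blobs_majority(rng):
    X, _ = blobs(rng, [20, 20, 20],
                 [np.zeros(4), np.full(4, 12.0), np.full(4, -12.0)])
    k, votes = choose_k(X)
    assert k == 3
    assert sum(v == 3 for v in votes.values()) > len(votes) / 2


def test_choose_k_degenerate_features_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        choose_k(np.ones((10, 3)))


def test_jaccard_separated_blobs_is_one(rng):
    X, _ = blobs(rng, [15, 20], [np.zeros(4), np.full(4, 15.0)])
    j = jaccard_stability(X, 2, n_boot=50, seed=1)
    assert j.shape == (2,)
    np.testing.assert_array_equal(j, 1.0)


def test_jaccard_noise_below_separated_case(rng):
    X = rng.standard_normal((40, 6))
    j = jaccard_stability(X, 2, n_boot=100, seed=2)
    assert np.all(j < 0.95)


def test_jaccard_reproducible_given_seed(rng):
    X = rng.standard_normal((25, 4))
    a = jaccard_stability(X, 2, n_boot=30, seed=5)
    b = jaccard_stability(X, 2, n_boot=30, seed=5)
    np.testing.assert_array_equal(a, b)


def test_ward_subtyper_estimator_interface(rng):
    X, truth = blobs(rng, [18, 22], [np.zeros(4), np.full(4, 10.0)])
    model = WardSubtyper(n_boot=25, random_state=3).fit(X)
    assert model.k_ == 2
    assert adjusted_rand_score(truth, model.labels_) == 1.0
    assert model.stable_.all()
    sol = model.solution()
    assert sol.to_dict()["cluster_sizes"] == [18, 22] or \
        sol.to_dict()["cluster_sizes"] == [22, 18]
    params = model.get_params()
    assert params["k_min"] == 2 and params["k_max"] == 6


@settings(deadline=None, derandomize=True, max_examples=30)
@given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1,
                max_size=50))
def test_bh_matches_brute_force_step_up(pvals):
    p = np.asarray(pvals)
    q = bh_fdr(p)
    m = len(p)
    order = np.argsort(p)
    brute = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        brute[idx] = running
    np.testing.assert_allclose(q, brute, atol=1e-12)


def _clinical_for(ids, rng, sexes=None):
    n = len(ids)
    sexes = sexes if sexes is not None else rng.choice(["male", "female"], n)
    return ClinicalTable(pd.DataFrame({
        "subject_id": ids,
        "group": ["patient"] * (n - 1) + ["control"],  # two labels required
        "caps": rng.uniform(50, 90, n),
        "age": rng.normal(43, 10, n),
        "sex": sexes,
    }))


def test_planted_edge_contrasts_found_with_correct_sign(rng):
    n1, n2, n_edges = 30, 30, 20
    X = rng.standard_normal((n1 + n2, n_edges))
    planted = [0, 3, 7, 11, 19]
    X[:n1, planted] += 3.0  # subtype 1 higher on exactly these edges
    labels = np.r_[np.ones(n1, int), np.full(n2, 2, int)]
    ids = [f"p{i}" for i in range(n1 + n2)]
    fm = FeatureMatrix(ids, [(e, e + 20) for e in range(n_edges)], X)
    res = contrast_subtypes(fm, labels, clinical=None)
    hits = set(np.flatnonzero(res.edge_table["q"] < 0.05))
    assert hits == set(planted)
    assert (res.edge_table.loc[planted, "t"] > 0).all()


def test_null_contrasts_control_fdr(rng):
    false_pos = 0
    total = 0
    for seed in range(30):
        r = np.random.default_rng(seed)
        X = r.standard_normal((40, 15))
        labels = np.r_[np.ones(20, int), np.full(20, 2, int)]
        fm = FeatureMatrix([f"p{i}" for i in range(40)],
                           [(e, e + 15) for e in range(15)], X)
        res = contrast_subtypes(fm, labels)
        false_pos += int(res.edge_table["significant"].sum())
        total += 15
    assert false_pos / total < 0.02  # BH keeps edge-wise false positives rare


def test_identical_feature_column_gives_t0_p1(rng):
    X = rng.standard_normal((20, 3))
    X[:, 1] = 4.2
    labels = np.r_[np.ones(10, int), np.full(10, 2, int)]
    fm = FeatureMatrix([f"p{i}" for i in range(20)],
                       [(0, 1), (0, 2), (1, 2)], X)
    res = contrast_subtypes(fm, labels)
    assert res.edge_table.loc[1, "t"] == 0.0
    assert res.edge_table.loc[1, "p"] == 1.0


def test_subtype_with_single_member_rejected(rng):
    X = rng.standard_normal((5, 2))
    labels = np.array([1, 1, 1, 1, 2])
    fm = FeatureMatrix([f"p{i}" for i in range(5)], [(0, 1), (0, 2)], X)
    with pytest.raises(ValueError, match="at least 2"):
        contrast_subtypes(fm, labels)


def test_clinical_and_interaction_tables(rng):
    n = 60
    ids = [f"p{i}" for i in range(n)]
    labels = np.r_[np.ones(n // 2, int), np.full(n // 2, 2, int)]
    sexes = np.tile(["male", "female"], n // 2)
    X = rng.standard_normal((n, 2))
    # plant a subgroup x sex interaction on edge 0
    mask = (labels == 1) & (sexes == "female")
    X[mask, 0] += 4.0
    fm = FeatureMatrix(ids, [(0, 1), (2, 3)], X)
    clinical = _clinical_for(ids, rng, sexes=sexes)
    res = contrast_subtypes(fm, labels, clinical)
    assert set(res.clinical_table["variable"]) >= {"caps", "age", "sex"}
    inter = res.interaction_table.set_index("edge")
    assert inter.loc["0-1", "p"] < 0.05
    assert "t=" in inter.loc["0-1", "posthoc"]
    assert inter.loc["2-3", "posthoc"] == ""
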