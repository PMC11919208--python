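import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from idscn import (
    IDSCN,
    ThicknessMatrix,
    build_edge_index,
    build_rscn,
    idscn_z,
    perturbed_scn,
    share_threshold,
    significant_edges,
    tally_and_select,
)
from idscn.core import IDSCNResult, ReferenceSCN


def brute_force_edges(M):
    return [(i, j) for i in range(M) for j in range(i + 1, M)]


def test_edge_index_counts_and_enumeration():
    assert build_edge_index(148).n_edges == 10878
    assert build_edge_index(2).pairs == [(0, 1)]
    idx5 = build_edge_index(5)
    assert idx5.n_edges == 10
    assert idx5.pairs == brute_force_edges(5)
    with pytest.raises(ValueError):
        build_edge_index(1)


@settings(deadline=None, derandomize=True)
@given(st.integers(min_value=2, max_value=30))
def test_linear_index_is_a_bijection(M):
    idx = build_edge_index(M)
    positions = [idx.linear_index(i, j) for i, j in brute_force_edges(M)]
    assert positions == list(range(idx.n_edges))
    # symmetric access
    assert idx.linear_index(M - 1, 0) == idx.linear_index(0, M - 1)


def test_rscn_matches_elementwise_pearson(rng):
    values = rng.standard_normal((10, 6))
    tm = ThicknessMatrix([f"s{i}" for i in range(10)],
                         [f"r{j}" for j in range(6)], values)
    ref = build_rscn(tm)
    for i in range(6):
        for j in range(6):
            r = stats.pearsonr(values[:, i], values[:, j])[0]
            assert abs(ref.corr[i, j] - r) < 1e-12
    assert ref.n == 10


def test_rscn_duplicate_and_anticorrelated_columns(rng):
    x = rng.standard_normal(8)
    values = np.column_stack([x, x, -x])
    tm = ThicknessMatrix([f"s{i}" for i in range(8)], ["a", "b", "c"], values)
    ref = build_rscn(tm)
    assert np.isclose(ref.corr[0, 1], 1.0)
    assert np.isclose(ref.corr[0, 2], -1.0)


def test_rscn_constant_column_names_region(rng):
    values = rng.standard_normal((6, 3))
    values[:, 1] = 2.5
    tm = ThicknessMatrix([f"s{i}" for i in range(6)], ["a", "bad", "c"], values)
    with pytest.raises(ValueError, match="bad"):
        build_rscn(tm)


def test_perturbed_scn_hand_calculation():
    controls = ThicknessMatrix(
        ["s0", "s1", "s2"], ["a", "b", "c"],
        np.array([[1.0, 2.0, 1.0], [2.0, 1.0, 3.0], [3.0, 4.0, 2.0]]),
    )
    patient = np.array([4.0, 3.0, 5.0])
    pscn = perturbed_scn(controls, patient)
    stacked = np.vstack([controls.values, patient])
    for i in range(3):
        for j in range(3):
            r = stats.pearsonr(stacked[:, i], stacked[:, j])[0]
            assert abs(pscn[i, j] - r) < 1e-12


def test_patient_at_control_means_barely_perturbs(rng):
    values = rng.standard_normal((50, 4))
    tm = ThicknessMatrix([f"s{i}" for i in range(50)],
                         [f"r{j}" for j in range(4)], values)
    ref = build_rscn(tm)
    pscn = perturbed_scn(tm, values.mean(axis=0))
    delta = np.abs(pscn - ref.corr)
    assert delta.max() < 0.02  # mean patient shifts correlations only O(1/n)


def test_z_formula_hand_value():
    """rSCN=0, n=89, delta=0.1 at one edge gives Z = 0.1 * 88 / 1 = 8.8."""
    M = 3
    ref = ReferenceSCN(corr=np.eye(M), n=89)
    pscn = np.eye(M)
    pscn[0, 1] = pscn[1, 0] = 0.1
    res = idscn_z(ref, pscn)
    assert np.isclose(res.z[0, 1], 8.8)
    assert np.isclose(res.z[1, 0], 8.8)
    assert (0, 1) in res.significant  # p << 0.05 / 3


def test_zero_delta_gives_zero_z_unit_p():
    corr = np.array([[1.0, 0.3], [0.3, 1.0]])
    res = idscn_z(ReferenceSCN(corr=corr, n=20), corr.copy())
    np.testing.assert_array_equal(res.z, np.zeros((2, 2)))
    np.testing.assert_array_equal(res.p, np.ones((2, 2)))
    assert res.significant == set()


def test_degenerate_unit_correlation_edge_excluded(rng):
    x = rng.standard_normal(12)
    y = rng.standard_normal(12)
    controls = ThicknessMatrix(
        [f"s{i}" for i in range(12)], ["a", "b", "c"],
        np.column_stack([x, 2 * x, y]),  # proportional pair -> r = 1 exactly
    )
    model = IDSCN().fit_thickness(controls)
    res = model.result_for(rng.standard_normal(3))
    assert (0, 1) in res.degenerate
    assert res.n_tests == 2  # 3 edges minus the degenerate one
    assert res.p[0, 1] == 1.0 and res.z[0, 1] == 0.0


def test_z_oracle_equivalence_small_instances(rng):
    """Z from the transformer equals independent edge-by-edge evaluation."""
    for _ in range(25):
        M = int(rng.integers(3, 7))
        n = int(rng.integers(5, 13))
        controls = rng.standard_normal((n, M))
        patient = rng.standard_normal(M)
        tm = ThicknessMatrix([f"s{i}" for i in range(n)],
                             [f"r{j}" for j in range(M)], controls)
        res = IDSCN().fit_thickness(tm).result_for(patient)
        stacked = np.vstack([controls, patient])
        for i in range(M):
            for j in range(i + 1, M):
                rr = stats.pearsonr(controls[:, i], controls[:, j])[0]
                rp = stats.pearsonr(stacked[:, i], stacked[:, j])[0]
                z = (rp - rr) / ((1 - rr ** 2) / (n - 1))
                assert abs(res.z[i, j] - z) < 1e-10


def test_z_symmetric_and_invariant_to_control_order(rng):
    controls = rng.standard_normal((15, 5))
    patient = rng.standard_normal(5)
    tm = ThicknessMatrix([f"s{i}" for i in range(15)],
                         [f"r{j}" for j in range(5)], controls)
    res = IDSCN().fit_thickness(tm).result_for(patient)
    np.testing.assert_allclose(res.z, res.z.T)
    perm = np.random.default_rng(0).permutation(15)
    tm2 = ThicknessMatrix([f"s{i}" for i in perm],
                          [f"r{j}" for j in range(5)], controls[perm])
    res2 = IDSCN().fit_thickness(tm2).result_for(patient)
    np.testing.assert_allclose(res.z, res2.z, atol=1e-12)


def test_significance_boundary_is_strict():
    M, n_tests = 3, 3
    alpha = 0.05
    z_at_threshold = stats.norm.isf(alpha / n_tests / 2)
    z = np.zeros((M, M))
    z[0, 1] = z[1, 0] = z_at_threshold
    p = np.ones((M, M))
    p[0, 1] = p[1, 0] = alpha / n_tests  # exactly the Bonferroni threshold
    res = IDSCNResult("p0", z=z, p=p, significant=set(), n_tests=n_tests)
    assert significant_edges(res, alpha, n_tests) == set()
    p[0, 1] = p[1, 0] = np.nextafter(alpha / n_tests, 0)
    assert significant_edges(res, alpha, n_tests) == {(0, 1)}


def test_all_unit_p_gives_empty_set():
    res = IDSCNResult("p0", z=np.zeros((4, 4)), p=np.ones((4, 4)),
                      significant=set(), n_tests=6)
    assert significant_edges(res, 0.05, 6) == set()


def test_share_threshold_values():
    assert share_threshold(89, 0.05) == 4   # 4.45 rounds down
    assert share_threshold(90, 0.05) == 5   # 4.5 rounds half away from zero
    assert share_threshold(10, 0.05) == 2   # floored at 2


def _result_with(M, significant, z_scale=5.0):
    z = np.zeros((M, M))
    p = np.ones((M, M))
    for i, j in significant:
        z[i, j] = z[j, i] = z_scale
        p[i, j] = p[j, i] = 1e-8
    return IDSCNResult("x", z=z, p=p, significant=set(significant),
                       n_tests=M * (M - 1) // 2)


def test_tally_dominant_edge_ranks_first():
    results = [_result_with(4, {(0, 1)}) for _ in range(6)]
    results += [_result_with(4, {(2, 3)}) for _ in range(3)]
    tally = tally_and_select(results, n_patients=9, share_fraction=0.3)
    assert tally.threshold == 3
    assert tally.top_edges[0] == (0, 1)
    assert tally.top_edges == [(0, 1), (2, 3)]


def test_tally_empty_when_no_edge_shared():
    results = [_result_with(4, set()) for _ in range(5)]
    tally = tally_and_select(results)
    assert tally.top_edges == []


def test_tally_tie_broken_by_mean_abs_z():
    results = [_result_with(4, {(0, 1)}, z_scale=2.0),
               _result_with(4, {(0, 1)}, z_scale=2.0),
               _result_with(4, {(1, 3)}, z_scale=9.0),
               _result_with(4, {(1, 3)}, z_scale=9.0)]
    tally = tally_and_select(results, n_patients=4, share_fraction=0.5)
    assert tally.top_edges == [(1, 3), (0, 1)]


def test_transformer_feature_order_matches_edge_index(small_cohort):
    controls, patients, _, _ = small_cohort
    model = IDSCN().fit_thickness(controls)
    Z = model.transform(patients.values)
    res0 = model.result_for(patients.values[0])
    np.testing.assert_array_equal(Z[0], model.edge_index_.vectorize(res0.z))
    # sklearn params round-trip
    assert IDSCN(alpha=0.01).get_params() == {"alpha": 0.01}
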