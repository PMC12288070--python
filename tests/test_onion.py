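"""Onion clustering: fixture recovery, run-length contract, scan behavior."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dynenv.datatypes import SignalEnsemble, combine
from dynenv.onion import (DeltaTScan, OnionClustering, OnionParams, default_grid,
                          delta_t_scan, onion_fit)
from dynenv.synthetic import (MarkovSpec, StateSpec, gen_state_ensemble,
                              three_state_chain, two_state_chain)


def assert_run_contract(labels, delta_t):
    """Every maximal classified run must last at least delta_t frames."""
    for row in labels:
        start = 0
        for i in range(1, len(row) + 1):
            if i == len(row) or row[i] != row[start]:
                if row[start] != -1:
                    assert i - start >= delta_t
                start = i


def test_params_validation():
    with pytest.raises(ValueError):
        OnionParams(delta_t=1)
    with pytest.raises(ValueError):
        OnionParams(min_population=0.0)
    with pytest.raises(ValueError):
        OnionParams(k_sigma=-1.0)
    with pytest.raises(ValueError):
        onion_fit(SignalEnsemble(values=np.zeros((3, 5))), OnionParams(delta_t=10))
    with pytest.raises(ValueError):
        OnionClustering().fit(np.empty((0, 0)))


def test_single_state_recovered(rng):
    spec = MarkovSpec([StateSpec(0.0, 0.2)], np.array([[1.0]]))
    ens, _ = gen_state_ensemble(spec, 100, 800, seed=1)
    res = onion_fit(ens, OnionParams(delta_t=10))
    assert res.n_states == 1
    se = 0.2 / np.sqrt(res.states[0].population * ens.values.size)
    assert abs(res.states[0].mean[0]) <= 3 * se
    assert res.env0_fraction <= 0.05
    assert_run_contract(res.labels, 10)


def test_two_static_groups(two_group_ensemble):
    res = onion_fit(two_group_ensemble, OnionParams(delta_t=10))
    assert res.n_states == 2
    means = sorted(float(s.mean[0]) for s in res.states)
    assert means[0] == pytest.approx(0.0, abs=0.01)
    assert means[1] == pytest.approx(5.0, abs=0.01)
    assert res.env0_fraction <= 0.01


def test_minority_below_population_filter_dissolved(rng):
    vals = np.concatenate([rng.normal(0.0, 0.1, (399, 500)),
                           rng.normal(5.0, 0.1, (1, 500))])
    res = onion_fit(SignalEnsemble(values=vals), OnionParams(delta_t=10))
    assert res.n_states == 1
    assert set(res.labels[-1]) == {-1}           # the minority series is ENV0


def test_three_state_resolution_depends_on_delta_t():
    ens, _ = gen_state_ensemble(three_state_chain(), 150, 3000, seed=21)
    r_fine = onion_fit(ens, OnionParams(delta_t=10))
    r_coarse = onion_fit(ens, OnionParams(delta_t=200))
    assert r_fine.n_states == 3
    assert r_coarse.n_states <= 2                # middle dwell ~50 frames
    assert_run_contract(r_fine.labels, 10)
    assert_run_contract(r_coarse.labels, 200)


def test_population_accounting(two_group_ensemble):
    res = onion_fit(two_group_ensemble, OnionParams(delta_t=25))
    total = sum(s.population for s in res.states) + res.env0_fraction
    assert total == pytest.approx(1.0, abs=1e-12)


def test_missing_values_break_runs_and_stay_env0(rng):
    vals = rng.normal(0.0, 0.1, (30, 300))
    vals[:, 100:105] = np.nan
    res = onion_fit(SignalEnsemble(values=vals), OnionParams(delta_t=50))
    assert np.all(res.labels[:, 100:105] == -1)
    assert_run_contract(res.labels, 50)


def test_delta_t_longer_than_series_errors(rng):
    ens = SignalEnsemble(values=rng.normal(size=(5, 20)))
    with pytest.raises(ValueError):
        onion_fit(ens, OnionParams(delta_t=30))


def test_full_length_delta_t_labels_whole_series(rng):
    ens, _ = gen_state_ensemble(two_state_chain(0.02), 50, 200, seed=5)
    res = onion_fit(ens, OnionParams(delta_t=200))
    for row in res.labels:
        assert len(set(row)) == 1                # all ENV0 or one state end-to-end


def test_determinism(two_group_ensemble):
    a = OnionClustering(delta_t=10).fit(two_group_ensemble.values)
    b = OnionClustering(delta_t=10).fit(two_group_ensemble.values.copy())
    assert np.array_equal(a.labels_, b.labels_)
    assert all(np.array_equal(x.mean, y.mean) for x, y in zip(a.states_, b.states_))


def test_separation_scaling_recovery_rate():
    # |Δmean|/σ = 6 exactly, dwells (100) well above 4·Δt
    spec = two_state_chain(p_switch=0.01, means=(0.0, 1.2), sigma=0.2)
    hits = 0
    for seed in range(20):
        ens, _ = gen_state_ensemble(spec, 50, 400, seed=seed)
        hits += onion_fit(ens, OnionParams(delta_t=20)).n_states == 2
    assert hits >= 19


@given(st.integers(0, 50))
@settings(max_examples=8, deadline=None, derandomize=True)
def test_run_contract_property(seed):
    ens, _ = gen_state_ensemble(two_state_chain(0.05), 20, 150, seed=seed)
    delta_t = 7 + seed % 20
    res = onion_fit(ens, OnionParams(delta_t=delta_t))
    assert_run_contract(res.labels, delta_t)
    total = sum(s.population for s in res.states) + res.env0_fraction
    assert total == pytest.approx(1.0, abs=1e-12)
    assert all(s.population >= 0.01 for s in res.states)


# ---------------------------------------------------------------------------
# bivariate

def test_bivariate_two_clusters(rng):
    n, t = 60, 400
    labels = (rng.random((n, 1)) < 0.5).astype(int)
    means = np.array([[0.0, 0.0], [4.0, 4.0]])
    vals = means[labels.ravel()][:, None, :] + rng.normal(0, 0.3, (n, t, 2))
    res = onion_fit(SignalEnsemble(values=vals), OnionParams(delta_t=10))
    assert res.n_states == 2
    got = sorted(tuple(np.round(s.mean, 1)) for s in res.states)
    assert got[0] == pytest.approx((0.0, 0.0), abs=0.1)
    assert got[1] == pytest.approx((4.0, 4.0), abs=0.1)


def test_bivariate_correlated_cluster(rng):
    # strongly correlated Gaussian: the fitted covariance must capture it
    n, t = 50, 300
    base = rng.normal(size=(n, t))
    vals = np.stack([base, base + 0.1 * rng.normal(size=(n, t))], axis=-1)
    res = onion_fit(SignalEnsemble(values=vals), OnionParams(delta_t=5))
    assert res.n_states == 1
    cov = res.states[0].cov
    corr = cov[0, 1] / np.sqrt(cov[0, 0] * cov[1, 1])
    assert corr > 0.98
    assert res.env0_fraction <= 0.05


# ---------------------------------------------------------------------------
# delta-t scan

def test_default_grid_properties():
    g = default_grid(1000)
    assert g[0] == 2 and g[-1] == 1000
    assert np.all(np.diff(g) > 0)


def test_scan_single_state_everywhere(rng):
    ens = SignalEnsemble(values=rng.normal(0.0, 0.3, (40, 300)))
    scan = delta_t_scan(ens, grid=np.array([2, 10, 50, 150, 300]))
    assert np.all(scan.n_states == 1)


def test_scan_static_groups_all_delta_t(two_group_ensemble):
    scan = delta_t_scan(two_group_ensemble, grid=np.array([2, 10, 100, 500]))
    assert np.all(scan.n_states == 2)


def test_scan_telegraph_drops_beyond_dwell():
    ens, _ = gen_state_ensemble(two_state_chain(0.01), 100, 2000, seed=3)
    scan = delta_t_scan(ens, grid=np.array([10, 50, 1000, 2000]))
    assert scan.n_states[0] == 2
    assert scan.n_states[1] == 2
    assert scan.n_states[-1] < 2                 # dwell ~100 frames
    assert isinstance(scan, DeltaTScan)
    assert np.allclose(scan.delta_t_time, scan.delta_t)   # dt_sample = 1
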