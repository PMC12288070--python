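"""SOAP descriptor: indexing conventions, expansion oracle, invariances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from dynenv.datatypes import ParticleTrajectory
from dynenv.soap import (SoapDescriptor, SoapParams, _basis_for, component_index,
                         cutoff_weight, descriptor_series, expansion_coefficients,
                         index_to_nnl, n_components, power_spectrum, real_sph_harm,
                         spherical_mask)


def quadrature_coefficients(center, neighbors, params, nr=200, nt=50, nph=100):
    """Independent oracle: dense 3D product-quadrature of <g_n Y_lm | rho>."""
    basis = _basis_for(params)
    xr, wr = np.polynomial.legendre.leggauss(nr)
    r = 0.5 * params.r_cut * (xr + 1.0)
    wr = 0.5 * params.r_cut * wr
    xc, wc = np.polynomial.legendre.leggauss(nt)
    theta = np.arccos(xc)
    phi_g = np.linspace(0, 2 * np.pi, nph, endpoint=False)
    wph = 2 * np.pi / nph
    R, TH, PH = np.meshgrid(r, theta, phi_g, indexing="ij")
    X = R * np.sin(TH) * np.cos(PH)
    Y = R * np.sin(TH) * np.sin(PH)
    Z = R * np.cos(TH)
    alpha = 1.0 / (2.0 * params.sigma_atom ** 2)
    rel = np.asarray(neighbors, dtype=float) - np.asarray(center, dtype=float)
    dens = np.zeros_like(R)
    for nb in rel:
        d = np.linalg.norm(nb)
        if d > params.r_cut:
            continue
        w = cutoff_weight(np.array([d]), params)[0]
        dens += w * np.exp(-alpha * ((X - nb[0]) ** 2 + (Y - nb[1]) ** 2 + (Z - nb[2]) ** 2))
    g = basis.g_of_r(r)
    W = wr[:, None, None] * R ** 2 * wc[None, :, None] * wph
    c = np.zeros((params.n_max, params.l_max + 1, 2 * params.l_max + 1))
    for n in range(params.n_max):
        for l in range(params.l_max + 1):
            for m in range(-l, l + 1):
                ylm = real_sph_harm(l, m, TH, PH)
                c[n, l, m + params.l_max] = np.sum(g[n][:, None, None] * ylm * dens * W)
    return c


# ---------------------------------------------------------------------------
# component indexing

@pytest.mark.parametrize("n,np_,l,n_max,l_max,expected", [
    (1, 1, 0, 8, 8, 0),
    (8, 8, 0, 8, 8, 63),        # the highest-variance spherical component
    (1, 1, 1, 8, 8, 64),
    (4, 4, 4, 4, 4, 79),
])
def test_component_index_convention(n, np_, l, n_max, l_max, expected):
    assert component_index(n, np_, l, n_max, l_max) == expected
    assert index_to_nnl(expected, n_max, l_max) == (n, np_, l)


def test_vector_lengths():
    assert n_components(8, 8) == 576
    assert n_components(4, 4) == 80


@given(st.integers(1, 8), st.integers(0, 8))
@settings(max_examples=20, deadline=None, derandomize=True)
def test_index_bijection(n_max, l_max):
    total = n_components(n_max, l_max)
    seen = set()
    for flat in range(total):
        n, np_, l = index_to_nnl(flat, n_max, l_max)
        assert component_index(n, np_, l, n_max, l_max) == flat
        seen.add((n, np_, l))
    assert len(seen) == total


def test_index_validation():
    with pytest.raises(ValueError):
        component_index(0, 1, 0, 8, 8)
    with pytest.raises(ValueError):
        component_index(1, 9, 0, 8, 8)
    with pytest.raises(ValueError):
        index_to_nnl(576, 8, 8)


def test_spherical_mask_counts():
    m88 = spherical_mask(8, 8)
    assert m88.sum() == 64 and m88[:64].all() and not m88[64:].any()
    assert spherical_mask(4, 4).sum() == 16
    # component #237 carries angular (l > 0) information
    assert not m88[237]
    assert index_to_nnl(237, 8, 8)[2] > 0


# ---------------------------------------------------------------------------
# expansion coefficients

PARAMS_SMALL = SoapParams(r_cut=4.0, n_max=2, l_max=2, sigma_atom=0.5)


def test_empty_neighborhood_is_zero():
    c = expansion_coefficients(np.zeros(3), np.empty((0, 3)), PARAMS_SMALL)
    assert np.all(c == 0)


def test_axial_symmetry_kills_m_nonzero():
    c = expansion_coefficients(np.zeros(3), np.array([[0.0, 0.0, 2.0]]), PARAMS_SMALL)
    for l in range(PARAMS_SMALL.l_max + 1):
        for m in range(-l, l + 1):
            if m != 0:
                assert np.allclose(c[:, l, m + PARAMS_SMALL.l_max], 0.0, atol=1e-14)


def test_coefficients_match_quadrature_oracle():
    neighbors = np.array([[0.0, 0.0, 2.0], [1.0, -0.5, 0.8], [-1.2, 0.7, -0.3]])
    c = expansion_coefficients(np.zeros(3), neighbors, PARAMS_SMALL)
    oracle = quadrature_coefficients(np.zeros(3), neighbors, PARAMS_SMALL)
    scale = np.abs(oracle).max()
    assert np.allclose(c, oracle, atol=1e-6 * scale, rtol=1e-6)


def test_single_neighbor_quadrature_oracle():
    neighbors = np.array([[0.0, 0.0, 2.0]])
    c = expansion_coefficients(np.zeros(3), neighbors, PARAMS_SMALL)
    oracle = quadrature_coefficients(np.zeros(3), neighbors, PARAMS_SMALL)
    nz = np.abs(oracle) > 1e-12
    assert np.max(np.abs(c[nz] - oracle[nz]) / np.abs(oracle[nz])) < 1e-6


def test_coefficient_additivity(rng):
    a = rng.normal(scale=1.2, size=(3, 3))
    b = rng.normal(scale=1.2, size=(2, 3))
    ca = expansion_coefficients(np.zeros(3), a, PARAMS_SMALL)
    cb = expansion_coefficients(np.zeros(3), b, PARAMS_SMALL)
    cab = expansion_coefficients(np.zeros(3), np.vstack([a, b]), PARAMS_SMALL)
    assert np.allclose(cab, ca + cb, rtol=1e-12, atol=1e-14)


def test_neighbors_beyond_cutoff_excluded():
    near = np.array([[1.0, 0.0, 0.0]])
    far = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 5.0]])   # 5 > r_cut = 4
    c1 = expansion_coefficients(np.zeros(3), near, PARAMS_SMALL)
    c2 = expansion_coefficients(np.zeros(3), far, PARAMS_SMALL)
    assert np.array_equal(c1, c2)


def test_include_center_adds_spherical_weight():
    params = SoapParams(r_cut=4.0, n_max=2, l_max=2, sigma_atom=0.5, include_center=True)
    c_on = expansion_coefficients(np.zeros(3), np.empty((0, 3)), params)
    assert np.any(c_on[:, 0, params.l_max] != 0)
    for l in range(1, params.l_max + 1):
        assert np.allclose(c_on[:, l, :], 0.0)


# ---------------------------------------------------------------------------
# power spectrum

def test_power_spectrum_zero_coeffs():
    c = np.zeros((2, 3, 5))
    assert np.all(power_spectrum(c, PARAMS_SMALL) == 0)


def test_power_spectrum_loop_oracle(rng):
    params = SoapParams(r_cut=4.0, n_max=2, l_max=1, sigma_atom=0.5)
    c = rng.normal(size=(2, 2, 3))
    p = power_spectrum(c, params)
    # element-by-element evaluation with explicit loops
    expected = np.empty(params.n_components)
    for l in range(params.l_max + 1):
        for n in range(1, params.n_max + 1):
            for np_ in range(1, params.n_max + 1):
                s = 0.0
                for m in range(-l, l + 1):
                    s += c[n - 1, l, m + params.l_max] * c[np_ - 1, l, m + params.l_max]
                flat = component_index(n, np_, l, params.n_max, params.l_max)
                expected[flat] = np.pi * np.sqrt(8.0 / (2 * l + 1)) * s
    assert np.allclose(p, expected, rtol=1e-14)


def test_power_spectrum_nnprime_symmetry(rng):
    params = SoapParams(r_cut=4.0, n_max=3, l_max=2, sigma_atom=0.5)
    c = rng.normal(size=(3, 3, 5))
    p = power_spectrum(c, params)
    for l in range(params.l_max + 1):
        for n in range(1, params.n_max + 1):
            for np_ in range(1, params.n_max + 1):
                i = component_index(n, np_, l, params.n_max, params.l_max)
                j = component_index(np_, n, l, params.n_max, params.l_max)
                assert p[i] == p[j]


# ---------------------------------------------------------------------------
# invariances of the full descriptor

def _random_neighborhood(rng, n):
    return rng.normal(scale=1.5, size=(n, 3))


def test_rotation_invariance(rng):
    est = SoapDescriptor(r_cut=5.0, n_max=3, l_max=3)
    for trial in range(10):
        neigh = _random_neighborhood(rng, 5)
        p0 = est.spectrum(np.zeros(3), neigh)
        rot = Rotation.random(random_state=trial).as_matrix()
        p1 = est.spectrum(np.zeros(3), neigh @ rot.T)
        assert np.max(np.abs(p1 - p0)) <= 1e-8 * max(np.max(np.abs(p0)), 1e-30)


def test_translation_invariance(rng):
    est = SoapDescriptor(r_cut=5.0, n_max=3, l_max=3)
    neigh = _random_neighborhood(rng, 5)
    shift = rng.normal(scale=30.0, size=3)
    p0 = est.spectrum(np.zeros(3), neigh)
    p1 = est.spectrum(shift, neigh + shift)
    assert np.max(np.abs(p1 - p0)) <= 1e-12 * max(np.max(np.abs(p0)), 1e-30)


def test_permutation_invariance(rng):
    est = SoapDescriptor(r_cut=5.0, n_max=3, l_max=3)
    neigh = _random_neighborhood(rng, 6)
    p0 = est.spectrum(np.zeros(3), neigh)
    p1 = est.spectrum(np.zeros(3), neigh[::-1])
    assert np.allclose(p0, p1, rtol=1e-12)


# ---------------------------------------------------------------------------
# descriptor series over trajectories

def test_descriptor_series_shape():
    rng = np.random.default_rng(0)
    pos = rng.random((10, 3, 3)) * 6.0
    traj = ParticleTrajectory(positions=pos, box=[6.0] * 3, periodic=[False] * 3)
    series = descriptor_series(traj, SoapParams(r_cut=3.0, n_max=4, l_max=4))
    assert series.values.shape == (10, 3, 80)
    assert series.components[0] == (1, 1, 0)
    assert series.components[79] == (4, 4, 4)


def test_frozen_lattice_descriptor_constant_in_time():
    grid = np.stack(np.meshgrid(*[np.arange(3)] * 3, indexing="ij"), -1).reshape(-1, 3) * 1.5
    pos = np.repeat(grid[:, None, :], 4, axis=1)
    traj = ParticleTrajectory(positions=pos, box=[4.5] * 3, periodic=[False] * 3)
    series = descriptor_series(traj, SoapParams(r_cut=2.0, n_max=2, l_max=2))
    assert np.allclose(series.values, series.values[:, :1, :])


def test_rigid_rotation_leaves_descriptor_constant(rng):
    base = rng.random((6, 3)) * 2.0 - 1.0
    frames = [base]
    for s in range(2):
        rot = Rotation.random(random_state=s).as_matrix()
        frames.append(base @ rot.T)
    pos = np.stack(frames, axis=1) + 5.0
    traj = ParticleTrajectory(positions=pos, box=[10.0] * 3, periodic=[False] * 3)
    series = descriptor_series(traj, SoapParams(r_cut=4.0, n_max=2, l_max=2))
    scale = np.abs(series.values).max()
    assert np.max(np.abs(series.values - series.values[:, :1, :])) <= 1e-8 * scale


def test_large_rcut_periodic_warns():
    pos = np.random.default_rng(3).random((4, 1, 3)) * 5.0
    traj = ParticleTrajectory(positions=pos, box=[5.0] * 3, periodic=[True] * 3)
    with pytest.warns(RuntimeWarning, match="minimum-image"):
        descriptor_series(traj, SoapParams(r_cut=4.0, n_max=2, l_max=1))


def test_params_validation():
    with pytest.raises(ValueError):
        SoapParams(r_cut=-1.0)
    with pytest.raises(ValueError):
        SoapParams(n_max=0)
    with pytest.raises(ValueError):
        SoapParams(sigma_atom=0.0)
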