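"""Single-species SOAP power spectra.

The local density around a center is the sum of Gaussians (width
``sigma_atom``) placed at every neighbor within ``r_cut``, tapered by a
smooth cutoff.  The density is expanded on an orthonormal radial basis
g_n(r) times real spherical harmonics Y_lm, and summarized by the
rotation-invariant power spectrum

    p_nn'l = pi * sqrt(8 / (2l + 1)) * sum_m c_nlm * c_n'lm

Component ordering (documented because published component numbers like
"#63" depend on it): l varies slowest; within each l-block the ordered
(n, n') pairs are laid out n-major; indices are 0-based.  Hence

    flat = l * n_max**2 + (n - 1) * n_max + (n' - 1)

which places (n = n' = n_max, l = 0) at flat index n_max**2 - 1 (63 for
n_max = 8) and gives vectors of length n_max**2 * (l_max + 1): 576 for
n_max = l_max = 8, 80 for n_max = l_max = 4.

The radial basis is a set of Gaussians with centers evenly spaced on
(0, r_cut], Löwdin-orthonormalized under the weight r^2 dr; angular
integrals use the closed form for a displaced Gaussian (modified
spherical Bessel functions), radial integrals Gauss–Legendre quadrature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, ive, sph_harm_y
from sklearn.base import BaseEstimator, TransformerMixin

from ._neighbors import displacements, neighbor_lists
from .datatypes import DescriptorSeries, ParticleTrajectory

__all__ = [
    "SoapParams", "SoapDescriptor", "component_index", "index_to_nnl",
    "n_components", "spherical_mask", "expansion_coefficients",
    "power_spectrum", "descriptor_series", "real_sph_harm",
]


# ---------------------------------------------------------------------------
# component indexing

def n_components(n_max: int, l_max: int) -> int:
    """Length of the power-spectrum vector: n_max^2 * (l_max + 1)."""
    return n_max * n_max * (l_max + 1)


def component_index(n: int, n_prime: int, l: int, n_max: int, l_max: int) -> int:
    """0-based flat index of component (n, n', l); n, n' are 1-based."""
    if not (1 <= n <= n_max and 1 <= n_prime <= n_max):
        raise ValueError(f"radial indices must lie in 1..{n_max}")
    if not (0 <= l <= l_max):
        raise ValueError(f"angular index must lie in 0..{l_max}")
    return l * n_max * n_max + (n - 1) * n_max + (n_prime - 1)


def index_to_nnl(flat: int, n_max: int, l_max: int) -> tuple[int, int, int]:
    """Inverse of :func:`component_index`."""
    total = n_components(n_max, l_max)
    if not 0 <= flat < total:
        raise ValueError(f"flat index must lie in 0..{total - 1}")
    l, rem = divmod(flat, n_max * n_max)
    n, n_prime = divmod(rem, n_max)
    return n + 1, n_prime + 1, l


def component_table(n_max: int, l_max: int) -> list[tuple[int, int, int]]:
    return [index_to_nnl(i, n_max, l_max) for i in range(n_components(n_max, l_max))]


def spherical_mask(n_max: int, l_max: int) -> np.ndarray:
    """Boolean flags per flat index, True where l = 0 (exactly n_max^2 of them)."""
    mask = np.zeros(n_components(n_max, l_max), dtype=bool)
    mask[: n_max * n_max] = True
    return mask


# ---------------------------------------------------------------------------
# real spherical harmonics

def real_sph_harm(l: int, m: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Real spherical harmonic Y_lm (theta = polar angle, phi = azimuth)."""
    if m == 0:
        return np.real(sph_harm_y(l, 0, theta, phi))
    y = sph_harm_y(l, abs(m), theta, phi)
    if m > 0:
        return np.sqrt(2.0) * (-1.0) ** m * np.real(y)
    return np.sqrt(2.0) * (-1.0) ** m * np.imag(y)


# ---------------------------------------------------------------------------
# parameters and the precomputed radial machinery

@dataclass
class SoapParams:
    """SOAP hyperparameters.

    r_cut : neighbor cutoff radius (length units; 10 Å for water-like data).
    n_max, l_max : radial / angular basis truncation.
    sigma_atom : Gaussian smearing width of the neighbor density.
    include_center : whether the center particle contributes to the density
        (only its l = 0 channel is defined); off by default — the described
        environment is "all other" particles.
    cutoff_smoothing : "cosine" tapers the density over the outer 10% of
        r_cut so the descriptor is continuous as neighbors cross the
        cutoff; "none" is a hard cutoff.
    normalize : optional unit-norm scaling of each power-spectrum vector.
    """

    r_cut: float = 10.0
    n_max: int = 8
    l_max: int = 8
    sigma_atom: float = 0.5
    include_center: bool = False
    cutoff_smoothing: str = "cosine"
    normalize: bool = False

    def __post_init__(self) -> None:
        if self.r_cut <= 0:
            raise ValueError("r_cut must be positive")
        if self.n_max < 1:
            raise ValueError("n_max must be >= 1")
        if self.l_max < 0:
            raise ValueError("l_max must be >= 0")
        if self.sigma_atom <= 0:
            raise ValueError("sigma_atom must be positive")
        if self.cutoff_smoothing not in ("cosine", "none"):
            raise ValueError("cutoff_smoothing must be 'cosine' or 'none'")

    @property
    def n_components(self) -> int:
        return n_components(self.n_max, self.l_max)


def cutoff_weight(r: np.ndarray, params: SoapParams) -> np.ndarray:
    """Smooth taper: 1 inside 0.9*r_cut, cosine decay to 0 at r_cut."""
    r = np.asarray(r, dtype=float)
    if params.cutoff_smoothing == "none":
        return (r <= params.r_cut).astype(float)
    r0 = 0.9 * params.r_cut
    w = np.ones_like(r)
    outer = (r > r0) & (r <= params.r_cut)
    w[outer] = 0.5 * (1.0 + np.cos(np.pi * (r[outer] - r0) / (params.r_cut - r0)))
    w[r > params.r_cut] = 0.0
    return w


class _RadialBasis:
    """Löwdin-orthonormalized Gaussian radial basis on (0, r_cut].

    Primitives: phi_k(r) = exp(-(r - r_k)^2 / (2 s^2)) with centers
    r_k = k * r_cut / n_max and width s = r_cut / n_max.  Orthonormality
    is under the measure r^2 dr on [0, r_cut], evaluated on the same
    Gauss–Legendre grid used for all radial integrals.
    """

    def __init__(self, params: SoapParams, n_quad: int = 128) -> None:
        self.params = params
        x, w = np.polynomial.legendre.leggauss(n_quad)
        self.r = 0.5 * params.r_cut * (x + 1.0)          # (Q,)
        self.w = 0.5 * params.r_cut * w
        self._centers = params.r_cut * np.arange(1, params.n_max + 1) / params.n_max
        self._width = params.r_cut / params.n_max
        prim = np.exp(-0.5 * ((self.r[None, :] - self._centers[:, None]) / self._width) ** 2)
        overlap = (prim * (self.w * self.r ** 2)[None, :]) @ prim.T
        evals, evecs = np.linalg.eigh(overlap)
        evals = np.maximum(evals, 1e-14 * evals.max())
        self._inv_sqrt = (evecs / np.sqrt(evals)) @ evecs.T   # S^{-1/2}, symmetric
        self.g = self._inv_sqrt @ prim                        # (n_max, Q) orthonormal

    def g_of_r(self, r: np.ndarray) -> np.ndarray:
        """Evaluate g_n at arbitrary radii (used by quadrature oracles)."""
        prim = np.exp(-0.5 * ((np.asarray(r, dtype=float)[None, :] - self._centers[:, None])
                              / self._width) ** 2)
        return self._inv_sqrt @ prim


_BASIS_CACHE: dict[tuple, _RadialBasis] = {}


def _basis_for(params: SoapParams) -> _RadialBasis:
    key = (params.r_cut, params.n_max, params.sigma_atom)
    if key not in _BASIS_CACHE:
        _BASIS_CACHE[key] = _RadialBasis(params)
    return _BASIS_CACHE[key]


def _scaled_spherical_iv(l: int, x: np.ndarray) -> np.ndarray:
    """exp(-x) * i_l(x), the exponentially scaled modified spherical Bessel
    function; stable for the large arguments that arise at r ~ r_cut."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = x < 1e-8
    if np.any(small):
        # i_l(x) ~ x^l / (2l+1)!!  as x -> 0
        log_dfact = gammaln(l + 1.5) - gammaln(1.5) + l * np.log(2.0)
        with np.errstate(divide="ignore"):
            out[small] = np.exp(l * np.log(np.maximum(x[small], 1e-300)) - log_dfact) if l else 1.0
    big = ~small
    if np.any(big):
        xb = x[big]
        out[big] = np.sqrt(np.pi / (2.0 * xb)) * ive(l + 0.5, xb)
    return out


# ---------------------------------------------------------------------------
# expansion coefficients and power spectrum

def expansion_coefficients(center: np.ndarray, neighbors: np.ndarray,
                           params: SoapParams) -> np.ndarray:
    """Real expansion coefficients c[n, l, m] of the smoothed neighbor density.

    ``neighbors`` are absolute positions; anything beyond r_cut is
    excluded here.  Returns an array of shape (n_max, l_max+1, 2*l_max+1)
    with the m axis offset so that c[:, l, m + l_max] holds m in -l..l.
    An empty neighborhood (and include_center False) yields all zeros.
    """
    basis = _basis_for(params)
    n_max, l_max = params.n_max, params.l_max
    c = np.zeros((n_max, l_max + 1, 2 * l_max + 1))

    center = np.asarray(center, dtype=float)
    rel = np.atleast_2d(np.asarray(neighbors, dtype=float)) - center \
        if np.size(neighbors) else np.empty((0, 3))
    if rel.size:
        dist = np.linalg.norm(rel, axis=1)
        at_center = dist < 1e-12
        n_at_center = int(at_center.sum())
        rel, dist = rel[~at_center], dist[~at_center]
        keep = dist <= params.r_cut
        rel, dist = rel[keep], dist[keep]
    else:
        dist = np.empty(0)
        n_at_center = 0

    alpha = 1.0 / (2.0 * params.sigma_atom ** 2)
    r_q, w_q = basis.r, basis.w

    if dist.size:
        f = cutoff_weight(dist, params)                              # (J,)
        theta = np.arccos(np.clip(rel[:, 2] / dist, -1.0, 1.0))
        phi = np.arctan2(rel[:, 1], rel[:, 0])
        # radial kernel shared across l: (J, Q)
        gauss = np.exp(-alpha * (r_q[None, :] - dist[:, None]) ** 2)
        x = 2.0 * alpha * r_q[None, :] * dist[:, None]
        wr2 = w_q * r_q ** 2
        for l in range(l_max + 1):
            kern = gauss * _scaled_spherical_iv(l, x) * wr2[None, :]  # (J, Q)
            radial = 4.0 * np.pi * (basis.g @ kern.T)                 # (n_max, J)
            for m in range(-l, l + 1):
                y = real_sph_harm(l, m, theta, phi)                   # (J,)
                c[:, l, m + l_max] += radial @ (f * y)

    # a Gaussian sitting exactly on the center has no direction and
    # contributes only to the spherically symmetric (l = 0) channel
    weight = n_at_center + (1.0 if params.include_center else 0.0)
    if weight:
        radial0 = np.sqrt(4.0 * np.pi) * (basis.g @ (w_q * r_q ** 2 * np.exp(-alpha * r_q ** 2)))
        c[:, 0, l_max] += weight * radial0
    return c


def power_spectrum(coeffs: np.ndarray, params: SoapParams) -> np.ndarray:
    """p_nn'l = pi * sqrt(8/(2l+1)) * sum_m c_nlm c_n'lm, flattened with
    the package ordering (l slowest, then n-major (n, n') pairs)."""
    n_max, l_max = params.n_max, params.l_max
    p = np.empty(params.n_components)
    for l in range(l_max + 1):
        cm = coeffs[:, l, l_max - l: l_max + l + 1]          # (n_max, 2l+1)
        block = np.pi * np.sqrt(8.0 / (2 * l + 1)) * (cm @ cm.T)
        p[l * n_max * n_max: (l + 1) * n_max * n_max] = block.ravel()
    if params.normalize:
        norm = np.linalg.norm(p)
        if norm > 0:
            p = p / norm
    return p


# ---------------------------------------------------------------------------
# sklearn-style descriptor

class SoapDescriptor(TransformerMixin, BaseEstimator):
    """Transformer mapping a :class:`ParticleTrajectory` to per-particle,
    per-frame SOAP power spectra (a :class:`DescriptorSeries` of shape
    N x T x n_max^2*(l_max+1)).

    Stateless: ``fit`` only validates parameters.  Neighbor searches
    respect the trajectory's periodic flags (minimum image).
    """

    def __init__(self, r_cut: float = 10.0, n_max: int = 8, l_max: int = 8,
                 sigma_atom: float = 0.5, include_center: bool = False,
                 cutoff_smoothing: str = "cosine", normalize: bool = False) -> None:
        self.r_cut = r_cut
        self.n_max = n_max
        self.l_max = l_max
        self.sigma_atom = sigma_atom
        self.include_center = include_center
        self.cutoff_smoothing = cutoff_smoothing
        self.normalize = normalize

    def _params(self) -> SoapParams:
        return SoapParams(r_cut=self.r_cut, n_max=self.n_max, l_max=self.l_max,
                          sigma_atom=self.sigma_atom, include_center=self.include_center,
                          cutoff_smoothing=self.cutoff_smoothing, normalize=self.normalize)

    def fit(self, X: ParticleTrajectory | None = None, y=None) -> "SoapDescriptor":
        params = self._params()
        self.n_components_ = params.n_components
        self.components_ = component_table(params.n_max, params.l_max)
        return self

    def spectrum(self, center: np.ndarray, neighbors: np.ndarray) -> np.ndarray:
        """Power spectrum of one explicit neighborhood (open boundaries)."""
        params = self._params()
        return power_spectrum(expansion_coefficients(center, neighbors, params), params)

    def transform(self, X: ParticleTrajectory) -> DescriptorSeries:
        params = self._params()
        self.fit(X)
        traj = X
        if traj.dim != 3:
            raise ValueError("SOAP descriptors require 3D trajectories")
        per = traj.periodic
        if per.any():
            half = 0.5 * traj.box[per].min()
            if params.r_cut > half:
                warnings.warn(
                    f"r_cut={params.r_cut} exceeds half the smallest periodic box "
                    f"length ({half}); minimum-image neighborhoods are ambiguous",
                    RuntimeWarning, stacklevel=2)
        n, t = traj.n_particles, traj.n_frames
        out = np.empty((n, t, params.n_components))
        for frame in range(t):
            pts = traj.frame(frame)
            lists = neighbor_lists(pts, params.r_cut, traj.box, per)
            for i in range(n):
                disp = displacements(pts[lists[i]], pts[i], traj.box, per)
                coeffs = expansion_coefficients(np.zeros(3), disp, params)
                out[i, frame] = power_spectrum(coeffs, params)
        return DescriptorSeries(values=out,
                                components=component_table(params.n_max, params.l_max),
                                provenance="raw", dt_sample=traj.dt_sample)


def descriptor_series(traj: ParticleTrajectory, params: SoapParams) -> DescriptorSeries:
    """Functional wrapper over :class:`SoapDescriptor`."""
    est = SoapDescriptor(r_cut=params.r_cut, n_max=params.n_max, l_max=params.l_max,
                         sigma_atom=params.sigma_atom, include_center=params.include_center,
                         cutoff_smoothing=params.cutoff_smoothing, normalize=params.normalize)
    return est.transform(traj)
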