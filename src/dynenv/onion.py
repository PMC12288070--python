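"""Onion clustering of signal ensembles at a fixed time resolution.

The algorithm classifies *stretches* of time-series, not single points.
Given the time resolution Δt (in frames), it iteratively peels Gaussian
states off the data density:

1. estimate the probability density of the still-unassigned points;
2. fit a Gaussian to the highest density peak (between its flanking
   local minima);
3. assign every maximal contiguous run of ≥ Δt frames whose values all
   stay within ``k_sigma`` spreads of the state (Mahalanobis distance in
   the multivariate case) to that state;
4. remove the assigned points and repeat until no candidate state gains
   at least ``min_population`` of all points.

After peeling, each state is re-fit on its assigned points (moment
estimates with a truncation correction) and all points are re-assigned
once from the refined states.  States whose final population falls
below ``min_population`` (default 1%) are dissolved into the
unclassified cluster ENV0 (label -1).  Because a run must survive Δt
frames inside a state, Δt is a *minimum dwell requirement*: short-lived
environments disappear as Δt grows, which is exactly what the Δt scan
(:func:`delta_t_scan`) measures.

NaN samples are never classified; they break runs and count toward ENV0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, ClusterMixin

from .datatypes import SignalEnsemble

__all__ = ["OnionParams", "OnionState", "OnionResult", "DeltaTScan",
           "OnionClustering", "onion_fit", "delta_t_scan", "default_grid"]

SIGMA_FLOOR = 1e-9
_KDE_MAX_POINTS = 20_000   # deterministic stride subsample for density estimates
_GRID_POINTS = 512


@dataclass
class OnionParams:
    """delta_t: window length in frames (>= 2).
    k_sigma: assignment half-width in units of the state spread.
    min_population: smallest fraction of all points a state may keep.
    max_states: safety cap on the number of peeled states."""

    delta_t: int = 10
    k_sigma: float = 3.0
    min_population: float = 0.01
    max_states: int = 20

    def __post_init__(self) -> None:
        if self.delta_t < 2:
            raise ValueError("delta_t must be >= 2 frames")
        if not 0.0 < self.min_population < 1.0:
            raise ValueError("min_population must lie in (0, 1)")
        if self.k_sigma <= 0:
            raise ValueError("k_sigma must be positive")
        if self.max_states < 1:
            raise ValueError("max_states must be >= 1")


@dataclass
class OnionState:
    """One Gaussian environment: mean, spread, fraction of all points."""

    mean: np.ndarray           # (d,)
    cov: np.ndarray            # (d, d); sigma**2 for univariate signals
    population: float = 0.0

    @property
    def sigma(self) -> float:
        """Scalar spread (sqrt of the leading covariance entry)."""
        return float(np.sqrt(self.cov[0, 0]))

    @property
    def ndim(self) -> int:
        return self.mean.shape[0]


@dataclass
class OnionResult:
    states: list[OnionState]
    labels: np.ndarray         # (N, T) ints, -1 = ENV0
    env0_fraction: float
    params: OnionParams

    @property
    def n_states(self) -> int:
        return len(self.states)


@dataclass
class DeltaTScan:
    """Cluster count and unclassified fraction across time resolutions."""

    delta_t: np.ndarray        # frames, strictly increasing
    n_states: np.ndarray
    env0_fraction: np.ndarray
    dt_sample: float = 1.0

    @property
    def delta_t_time(self) -> np.ndarray:
        return self.delta_t * self.dt_sample


# ---------------------------------------------------------------------------
# internals

def _run_mask(mask: np.ndarray, min_len: int) -> np.ndarray:
    """Points belonging to maximal contiguous True-runs of length >= min_len
    (runs never cross series boundaries)."""
    n, t = mask.shape
    flat = np.column_stack([mask, np.zeros(n, dtype=bool)]).ravel()
    d = np.diff(flat.astype(np.int8), prepend=np.int8(0))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    lengths = ends - starts
    ok = lengths >= min_len
    out = np.zeros(flat.size, dtype=bool)
    if ok.any():
        starts, lengths = starts[ok], lengths[ok]
        offsets = np.arange(lengths.sum()) - np.repeat(np.cumsum(lengths) - lengths, lengths)
        out[np.repeat(starts, lengths) + offsets] = True
    return out.reshape(n, t + 1)[:, :t]


def _subsample(pts: np.ndarray) -> np.ndarray:
    stride = max(1, len(pts) // _KDE_MAX_POINTS)
    return pts[::stride]


def _gauss(x, a, mu, sigma):
    return a * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def _moment_polish(sub: np.ndarray, mean: np.ndarray, cov: np.ndarray,
                   k_sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """Self-consistent truncated-moment iteration around one density peak.

    Density-based peak fits are biased — KDE bandwidths oversmooth
    multimodal data, axis-aligned histogram boxes truncate correlated
    clusters — so the (mean, cov) guess is polished by iterating: select
    the points within Mahalanobis k_sigma, re-estimate moments with the
    truncation correction, repeat.  At the fixed point the selected set
    is exactly the k_sigma truncation of the fitted Gaussian."""
    d = sub.shape[1]
    for _ in range(30):
        evals, evecs = np.linalg.eigh(cov)
        evals = np.maximum(evals, SIGMA_FLOOR ** 2)
        z = (sub - mean) @ evecs / np.sqrt(evals)
        picked = sub[np.einsum("ij,ij->i", z, z) <= k_sigma ** 2]
        if len(picked) < d + 2:
            break
        new_mean = picked.mean(axis=0)
        new_cov = _floor_cov(np.atleast_2d(np.cov(picked, rowvar=False))
                             / _truncation_factor(k_sigma, _effective_dim(cov)))
        shift = np.linalg.norm(new_mean - mean) + np.linalg.norm(new_cov - cov)
        scale = np.linalg.norm(cov) + SIGMA_FLOOR
        mean, cov = new_mean, new_cov
        if shift / scale < 1e-3:
            break
    return mean, cov


def _fit_peak_1d(pts: np.ndarray, k_sigma: float) -> tuple[float, float]:
    """Gaussian (mean, sigma) fitted to the highest peak of a KDE of the
    points (restricted to the density between the flanking local minima),
    then polished by the truncated-moment iteration — the Silverman
    bandwidth alone oversmooths each peak of a multimodal density."""
    sub = _subsample(pts)
    spread = sub.max() - sub.min()
    if spread < 10 * SIGMA_FLOOR:
        return float(sub[0]), SIGMA_FLOOR
    kde = stats.gaussian_kde(sub, bw_method="silverman")
    pad = 0.05 * spread
    grid = np.linspace(sub.min() - pad, sub.max() + pad, _GRID_POINTS)
    dens = kde(grid)
    ipk = int(np.argmax(dens))
    il = ipk
    while il > 0 and dens[il - 1] < dens[il]:
        il -= 1
    ir = ipk
    while ir < dens.size - 1 and dens[ir + 1] < dens[ir]:
        ir += 1
    x, y = grid[il:ir + 1], dens[il:ir + 1]
    w = y.sum()
    mu0 = float((x * y).sum() / w)
    var0 = float((y * (x - mu0) ** 2).sum() / w)
    sigma0 = max(np.sqrt(var0), SIGMA_FLOOR)
    try:
        popt, _ = optimize.curve_fit(
            _gauss, x, y, p0=(dens[ipk], grid[ipk], sigma0),
            bounds=([0.0, x[0], SIGMA_FLOOR], [np.inf, x[-1], np.inf]),
            maxfev=2000)
        mu, sigma = float(popt[1]), float(abs(popt[2]))
    except (RuntimeError, ValueError):
        mu, sigma = mu0, sigma0   # moment fallback on the windowed density
    mean, cov = _moment_polish(sub[:, None], np.array([mu]),
                               np.array([[max(sigma, SIGMA_FLOOR) ** 2]]), k_sigma)
    return float(mean[0]), max(float(np.sqrt(cov[0, 0])), SIGMA_FLOOR)


def _fd_edges(col: np.ndarray, max_bins: int = 64, min_bins: int = 8) -> np.ndarray:
    q75, q25 = np.percentile(col, [75, 25])
    iqr = q75 - q25
    lo, hi = col.min(), col.max()
    span = hi - lo
    if span <= 0 or iqr <= 0:
        return np.linspace(lo - 0.5, hi + 0.5, min_bins + 1)
    width = 2.0 * iqr / max(len(col), 2) ** (1.0 / 3.0)    # Freedman-Diaconis
    bins = int(np.clip(np.ceil(span / width), min_bins, max_bins))
    return np.linspace(lo, hi, bins + 1)


def _fit_peak_nd(pts: np.ndarray, k_sigma: float) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian (mean, cov) around the highest peak of a d-dimensional
    histogram.

    The peak bin and the flanking local minima along each axis give a
    first (mean, cov) guess; because axis-aligned boxes truncate
    correlated clusters badly, the estimate is then polished by a
    self-consistent truncated-moment iteration: select points within
    Mahalanobis k_sigma, re-estimate moments with the truncation
    correction, repeat to convergence.  At the fixed point the selection
    is exactly the k_sigma truncation of the fitted Gaussian."""
    d = pts.shape[1]
    spreads = pts.max(axis=0) - pts.min(axis=0)
    if np.all(spreads < 10 * SIGMA_FLOOR):
        return pts[0].copy(), np.eye(d) * SIGMA_FLOOR ** 2
    sub = _subsample(pts)
    edges = [_fd_edges(sub[:, j]) for j in range(d)]
    hist, edges = np.histogramdd(sub, bins=edges)
    peak = np.unravel_index(int(np.argmax(hist)), hist.shape)
    lo = np.empty(d)
    hi = np.empty(d)
    for ax in range(d):
        sl = list(peak)
        sl[ax] = slice(None)
        prof = hist[tuple(sl)]
        il = peak[ax]
        while il > 0 and prof[il - 1] < prof[il]:
            il -= 1
        ir = peak[ax]
        while ir < prof.size - 1 and prof[ir + 1] < prof[ir]:
            ir += 1
        lo[ax], hi[ax] = edges[ax][il], edges[ax][ir + 1]
    inside = np.all((sub >= lo) & (sub <= hi), axis=1)
    sel = sub[inside] if inside.sum() >= d + 2 else sub
    mean = sel.mean(axis=0)
    cov = _floor_cov(np.atleast_2d(np.cov(sel, rowvar=False)))
    return _moment_polish(sub, mean, cov, k_sigma)


def _floor_cov(cov: np.ndarray) -> np.ndarray:
    evals, evecs = np.linalg.eigh(cov)
    evals = np.maximum(evals, SIGMA_FLOOR ** 2)
    return (evecs * evals) @ evecs.T


def _truncation_factor(k_sigma: float, d_eff: int) -> float:
    """Variance shrinkage of a standard normal truncated to Mahalanobis
    distance <= k in d_eff effective dimensions:
    E[X^2_per-dim | chi2_d <= k^2] = F_{d+2}(k^2) / F_d(k^2)."""
    k2 = k_sigma ** 2
    denom = stats.chi2.cdf(k2, d_eff)
    if denom <= 0:
        return 1.0
    return float(stats.chi2.cdf(k2, d_eff + 2) / denom)


def _effective_dim(cov: np.ndarray) -> int:
    evals = np.linalg.eigvalsh(cov)
    return max(1, int(np.sum(evals > max(evals.max() * 1e-10, SIGMA_FLOOR ** 2 * 10))))


def _in_window(values: np.ndarray, state: OnionState, k_sigma: float) -> np.ndarray:
    """(N, T) bool: whole signal vector within k_sigma of the state."""
    if values.ndim == 2:
        sigma = max(state.sigma, SIGMA_FLOOR)
        with np.errstate(invalid="ignore"):
            return np.abs(values - state.mean[0]) <= k_sigma * sigma
    dev = values - state.mean                       # (N, T, d)
    evals, evecs = np.linalg.eigh(state.cov)
    evals = np.maximum(evals, SIGMA_FLOOR ** 2)
    z = dev @ evecs / np.sqrt(evals)
    with np.errstate(invalid="ignore"):
        return np.einsum("ntd,ntd->nt", z, z) <= k_sigma ** 2


def _refit(values: np.ndarray, mask: np.ndarray, state: OnionState,
           k_sigma: float) -> OnionState:
    """Moment re-fit of a state on its assigned points, corrected for the
    truncation imposed by the assignment window."""
    pts = values[mask]
    if pts.size == 0:
        return state
    if values.ndim == 2:
        mean = np.array([pts.mean()])
        var = pts.var(ddof=1) if pts.size > 1 else SIGMA_FLOOR ** 2
        var /= _truncation_factor(k_sigma, 1)
        cov = np.array([[max(var, SIGMA_FLOOR ** 2)]])
    else:
        mean = pts.mean(axis=0)
        cov = np.atleast_2d(np.cov(pts, rowvar=False)) if len(pts) > pts.shape[1] + 1 \
            else state.cov
        cov = _floor_cov(cov / _truncation_factor(k_sigma, _effective_dim(cov)))
    return OnionState(mean=mean, cov=cov, population=state.population)


# ---------------------------------------------------------------------------
# the estimator

class OnionClustering(ClusterMixin, BaseEstimator):
    """Single-point time-series clustering at a fixed time resolution.

    Parameters follow :class:`OnionParams`.  ``fit`` accepts an
    (n_series, n_frames) array for univariate signals or an
    (n_series, n_frames, d) array for multivariate ones (NaN = missing).

    Attributes (after fit): ``states_`` (list of :class:`OnionState`,
    ordered by ascending mean), ``labels_`` ((N, T) ints, -1 = ENV0),
    ``env0_fraction_``, ``n_states_``.
    """

    def __init__(self, delta_t: int = 10, k_sigma: float = 3.0,
                 min_population: float = 0.01, max_states: int = 20) -> None:
        self.delta_t = delta_t
        self.k_sigma = k_sigma
        self.min_population = min_population
        self.max_states = max_states

    def _params(self) -> OnionParams:
        return OnionParams(delta_t=self.delta_t, k_sigma=self.k_sigma,
                           min_population=self.min_population, max_states=self.max_states)

    def fit(self, X, y=None) -> "OnionClustering":
        params = self._params()
        values = np.asarray(X, dtype=float)
        if isinstance(X, SignalEnsemble):
            values = X.values
        if values.ndim not in (2, 3):
            raise ValueError("X must have shape (N, T) or (N, T, d)")
        if values.size == 0:
            raise ValueError("empty ensemble")
        n, t = values.shape[:2]
        if params.delta_t > t:
            raise ValueError(f"delta_t={params.delta_t} exceeds the series length {t}")

        finite = np.isfinite(values) if values.ndim == 2 \
            else np.all(np.isfinite(values), axis=2)
        total = n * t
        unassigned = finite.copy()
        labels = np.full((n, t), -1, dtype=int)
        states: list[OnionState] = []

        # --- peeling ---
        # points inside an already-peeled state's window that failed the
        # run-length requirement would dominate the density again and make
        # the peak search re-discover the same state forever; they are
        # masked out of the *density estimate* (never out of assignment)
        density_excluded = np.zeros_like(unassigned)
        for _ in range(5 * params.max_states):
            if len(states) >= params.max_states:
                break
            sel = values[unassigned & ~density_excluded]
            if sel.shape[0] < max(2, int(params.min_population * total)):
                break
            if values.ndim == 2:
                mu, sigma = _fit_peak_1d(sel, params.k_sigma)
                state = OnionState(mean=np.array([mu]), cov=np.array([[sigma ** 2]]))
            else:
                mean, cov = _fit_peak_nd(sel, params.k_sigma)
                state = OnionState(mean=mean, cov=cov)
            # a candidate whose mean falls inside an existing state's window
            # duplicates that state (its peak is residue of an earlier peel):
            # its points extend the existing state instead of founding a new one
            target = len(states)
            for i, prev in enumerate(states):
                if _in_window(state.mean[None, None, :] if values.ndim == 3
                              else state.mean[None, :], prev, params.k_sigma).ravel()[0]:
                    target = i
                    break
            window = _in_window(values, state, params.k_sigma) & unassigned
            assigned = _run_mask(window, params.delta_t)
            gained = int(assigned.sum())
            if gained < params.min_population * total:
                # this peak cannot found (or extend) a significant state:
                # drop its window from the density and search for the next
                # peak; stop once no classifiable density remains
                fresh = window & ~density_excluded
                if not fresh.any():
                    break
                density_excluded |= window
                continue
            labels[assigned] = target
            unassigned &= ~assigned
            if target == len(states):
                states.append(state)

        # --- refinement: re-fit states on their assigned points (moment
        # estimates with truncation correction) and re-assign everything
        # from scratch, iterated to a fixed point of the labels ---
        for _ in range(10):
            states = [_refit(values, labels == i, st, params.k_sigma)
                      for i, st in enumerate(states)]
            new_labels = np.full((n, t), -1, dtype=int)
            unassigned = finite.copy()
            for i, state in enumerate(states):
                window = _in_window(values, state, params.k_sigma) & unassigned
                assigned = _run_mask(window, params.delta_t)
                new_labels[assigned] = i
                unassigned &= ~assigned
                state.population = float(assigned.sum()) / total
            stable = bool(np.array_equal(new_labels, labels))
            labels = new_labels
            if stable:
                break

        # --- dissolve statistically insignificant states into ENV0, then
        # order the survivors by ascending mean (lexicographic) ---
        keep = [i for i, st in enumerate(states) if st.population >= params.min_population]
        keep.sort(key=lambda i: tuple(states[i].mean))
        lookup = np.full(len(states) + 1, -1, dtype=int)       # last slot = ENV0
        for new, old in enumerate(keep):
            lookup[old] = new
        labels = lookup[labels]                                # -1 indexes the last slot
        states = [states[i] for i in keep]

        self.states_ = states
        self.labels_ = labels
        self.n_states_ = len(states)
        self.env0_fraction_ = float(np.mean(labels == -1))
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).labels_

    def result(self) -> OnionResult:
        return OnionResult(states=self.states_, labels=self.labels_,
                           env0_fraction=self.env0_fraction_, params=self._params())


def onion_fit(ensemble: SignalEnsemble, params: OnionParams | None = None) -> OnionResult:
    """Functional wrapper over :class:`OnionClustering`."""
    params = params or OnionParams()
    est = OnionClustering(delta_t=params.delta_t, k_sigma=params.k_sigma,
                          min_population=params.min_population,
                          max_states=params.max_states)
    est.fit(ensemble.values)
    return est.result()


def default_grid(n_frames: int, n_points: int = 30) -> np.ndarray:
    """Log-spaced integer Δt grid from 2 frames to the full series length."""
    if n_frames < 4:
        raise ValueError("need at least 4 frames for a Δt scan")
    grid = np.unique(np.round(np.geomspace(2, n_frames, n_points)).astype(int))
    grid = np.unique(np.concatenate([[2], grid, [n_frames]]))
    return grid[(grid >= 2) & (grid <= n_frames)]


def delta_t_scan(ensemble: SignalEnsemble, grid: np.ndarray | None = None,
                 k_sigma: float = 3.0, min_population: float = 0.01,
                 max_states: int = 20) -> DeltaTScan:
    """Onion clustering at every Δt of a (default log-spaced) grid."""
    t = ensemble.n_frames
    grid = default_grid(t) if grid is None else np.asarray(grid, dtype=int)
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("Δt grid must be strictly increasing")
    n_states = np.empty(grid.size, dtype=int)
    env0 = np.empty(grid.size)
    for i, dt in enumerate(grid):
        res = onion_fit(ensemble, OnionParams(delta_t=int(dt), k_sigma=k_sigma,
                                              min_population=min_population,
                                              max_states=max_states))
        n_states[i] = res.n_states
        env0[i] = res.env0_fraction
    return DeltaTScan(delta_t=grid, n_states=n_states, env0_fraction=env0,
                      dt_sample=ensemble.dt_sample)
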