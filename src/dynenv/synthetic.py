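"""Synthetic generators with ground-truth labels.

Three families of inputs are emulated, matching the statistical structure
the downstream analysis assumes:

* ensembles of scalar/vector signals with Markov switching between
  Gaussian emission states and controllable dwell times;
* a two-phase particle system — a near-static lattice slab, a diffusing
  liquid-like region, and an exchanging interface layer;
* a 2D particle field traversed by a coherent velocity wave (an
  active-matter, Quincke-roller-like analogue).

Every generator takes a single integer seed; one master ``SeedSequence``
spawns independent substreams per purpose (state path vs emission noise)
so that changing one stream never perturbs the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import ParticleTrajectory, SignalEnsemble

SIGMA_FLOOR = 1e-9  # emission sigma of exactly 0 is floored to this


@dataclass
class StateSpec:
    """One Gaussian emission state: mean (scalar or d-vector), spread, label."""

    mean: float | np.ndarray
    sigma: float | np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.sigma = np.atleast_1d(np.asarray(self.sigma, dtype=float))
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be >= 0")
        self.sigma = np.maximum(self.sigma, SIGMA_FLOOR)
        if self.sigma.shape not in ((1,), self.mean.shape):
            raise ValueError("sigma must be scalar or match mean in shape")

    @property
    def ndim(self) -> int:
        return self.mean.shape[0]


@dataclass
class MarkovSpec:
    """Discrete-time Markov chain over Gaussian emission states.

    ``transition_matrix`` holds per-frame transition probabilities; the
    mean dwell time of state k is 1/(1 - T_kk) frames.
    """

    states: list[StateSpec]
    transition_matrix: np.ndarray
    initial_distribution: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.states:
            raise ValueError("need at least one state")
        d = self.states[0].ndim
        if any(s.ndim != d for s in self.states):
            raise ValueError("all states must share the same dimensionality")
        k = len(self.states)
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        if self.transition_matrix.shape != (k, k):
            raise ValueError("transition matrix must be (K, K)")
        if np.any(self.transition_matrix < 0) or np.any(self.transition_matrix > 1):
            raise ValueError("transition probabilities must lie in [0, 1]")
        rows = self.transition_matrix.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-12):
            raise ValueError("transition matrix rows must sum to 1")
        if self.initial_distribution is None:
            self.initial_distribution = self.stationary_distribution()
        else:
            self.initial_distribution = np.asarray(self.initial_distribution, dtype=float)
            if self.initial_distribution.shape != (k,):
                raise ValueError("initial distribution must have one entry per state")
            if np.any(self.initial_distribution < 0) or abs(self.initial_distribution.sum() - 1.0) > 1e-12:
                raise ValueError("initial distribution must be a probability vector")

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def ndim(self) -> int:
        return self.states[0].ndim

    def mean_dwell(self, k: int) -> float:
        """Mean sojourn of state k in frames: 1/(1 - T_kk)."""
        stay = self.transition_matrix[k, k]
        return np.inf if stay >= 1.0 else 1.0 / (1.0 - stay)

    def stationary_distribution(self) -> np.ndarray:
        """Left eigenvector of the transition matrix for eigenvalue 1."""
        w, v = np.linalg.eig(self.transition_matrix.T)
        i = int(np.argmin(np.abs(w - 1.0)))
        pi = np.real(v[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()


def two_state_chain(p_switch: float = 0.01, means: tuple[float, float] = (0.0, 5.0),
                    sigma: float = 0.1) -> MarkovSpec:
    """Symmetric telegraph process: mean dwell = 1/p_switch frames."""
    t = np.array([[1 - p_switch, p_switch], [p_switch, 1 - p_switch]])
    states = [StateSpec(m, sigma, name=f"S{i}") for i, m in enumerate(means)]
    return MarkovSpec(states, t)


def three_state_chain(means: tuple[float, float, float] = (-2.0, 0.0, 2.0),
                      sigma: float = 0.25, middle_dwell: float = 50.0,
                      outer_dwell: float = 1000.0) -> MarkovSpec:
    """Two long-lived outer states linked by a short-lived middle state.

    The middle state plays the role of an interfacial environment: its
    dwell time bounds the time resolution at which it stays detectable.
    Exits from the middle state split evenly between the outer two.
    """
    p_out = 1.0 / outer_dwell
    p_mid = 1.0 / middle_dwell
    t = np.array([
        [1 - p_out, p_out, 0.0],
        [p_mid / 2, 1 - p_mid, p_mid / 2],
        [0.0, p_out, 1 - p_out],
    ])
    states = [StateSpec(m, sigma, name=n) for m, n in zip(means, ("low", "mid", "high"))]
    return MarkovSpec(states, t)


def gen_state_ensemble(spec: MarkovSpec, n_series: int, n_frames: int,
                       seed: int) -> tuple[SignalEnsemble, np.ndarray]:
    """Simulate ``n_series`` independent Markov chains with Gaussian emissions.

    Returns the ensemble (univariate → (N, T); d-variate → (N, T, d)) and
    the generating state label per frame, an (N, T) int array.
    """
    if n_series < 1:
        raise ValueError("n_series must be >= 1")
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    ss_path, ss_emit = np.random.SeedSequence(seed).spawn(2)
    rng_path = np.random.default_rng(ss_path)
    rng_emit = np.random.default_rng(ss_emit)

    k = spec.n_states
    labels = np.empty((n_series, n_frames), dtype=int)
    cum0 = np.cumsum(spec.initial_distribution)
    labels[:, 0] = np.searchsorted(cum0, rng_path.random(n_series), side="right").clip(max=k - 1)
    cum = np.cumsum(spec.transition_matrix, axis=1)
    for t in range(1, n_frames):
        u = rng_path.random(n_series)
        rows = cum[labels[:, t - 1]]
        labels[:, t] = (u[:, None] >= rows).sum(axis=1).clip(max=k - 1)

    d = spec.ndim
    means = np.stack([s.mean for s in spec.states])            # (K, d)
    sigmas = np.stack([np.broadcast_to(s.sigma, (d,)) for s in spec.states])
    noise = rng_emit.standard_normal((n_series, n_frames, d))
    values = means[labels] + sigmas[labels] * noise
    if d == 1:
        values = values[:, :, 0]
    return SignalEnsemble(values=values, name="markov_ensemble"), labels


def gen_two_phase_toy(n_solid: int = 125, n_liquid: int = 125, n_frames: int = 100,
                      lattice_const: float = 1.0, jitter_sigma: float = 0.05,
                      walk_sigma: float = 0.15, exchange_prob: float = 0.02,
                      seed: int = 0, dim: int = 3,
                      dt_sample: float = 1.0) -> tuple[ParticleTrajectory, np.ndarray]:
    """Two coexisting phases plus an exchanging interface layer.

    Solid particles sit on a cubic lattice slab (anchor + i.i.d. Gaussian
    jitter each frame); liquid particles perform a reflected random walk
    in the remaining volume at roughly half the solid number density.
    Particles within one lattice constant of the slab face may swap
    behaviour with probability ``exchange_prob`` per frame, emulating
    molecular exchange at a solid/liquid interface.  Phase labels
    (0 = solid-like, 1 = liquid-like) track the *current* behaviour.
    """
    if n_solid < 0 or n_liquid < 0:
        raise ValueError("particle counts must be >= 0")
    if n_solid + n_liquid == 0:
        raise ValueError("need at least one particle")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if lattice_const <= 0:
        raise ValueError("lattice_const must be positive")
    if dim not in (2, 3):
        raise ValueError("dim must be 2 or 3")
    if not 0.0 <= exchange_prob <= 1.0:
        raise ValueError("exchange_prob must be a probability")

    a = lattice_const
    m = max(1, int(np.ceil(n_solid ** (1.0 / dim))))           # cross-section sites
    layers = max(1, int(np.ceil(n_solid / m ** (dim - 1)))) if n_solid else 1
    cross = m * a
    slab_x = layers * a
    # liquid sized to ~half the solid number density
    liquid_x = max(2 * a, 2.0 * n_liquid * a ** dim / cross ** (dim - 1))
    box = np.array([slab_x + liquid_x] + [cross] * (dim - 1))
    if np.any(box <= 0):
        raise ValueError("degenerate box")

    ss_path, ss_noise = np.random.SeedSequence(seed).spawn(2)
    rng_path = np.random.default_rng(ss_path)
    rng_noise = np.random.default_rng(ss_noise)

    grids = np.meshgrid(*([np.arange(m)] * (dim - 1)), np.arange(layers), indexing="ij")
    sites = (np.stack([g.ravel() for g in grids[::-1]], axis=1)[:n_solid] + 0.5) * a
    # first column is the slab axis (x)
    anchors = np.zeros((n_solid, dim))
    anchors[:, 0] = sites[:, 0]
    anchors[:, 1:] = sites[:, 1:]

    n = n_solid + n_liquid
    pos = np.empty((n, n_frames, dim))
    labels = np.empty((n, n_frames), dtype=int)
    cur_anchor = np.zeros((n, dim))
    cur_anchor[:n_solid] = anchors
    solid = np.zeros(n, dtype=bool)
    solid[:n_solid] = True

    cur = np.empty((n, dim))
    cur[:n_solid] = anchors
    cur[n_solid:, 0] = slab_x + rng_path.random((n_liquid,)) * liquid_x
    cur[n_solid:, 1:] = rng_path.random((n_liquid, dim - 1)) * cross

    for t in range(n_frames):
        if t > 0:
            if exchange_prob > 0:
                near = np.abs(cur[:, 0] - slab_x) <= a
                flip = near & (rng_path.random(n) < exchange_prob)
                to_liquid = flip & solid
                to_solid = flip & ~solid
                solid[to_liquid] = False
                solid[to_solid] = True
                cur_anchor[to_solid] = cur[to_solid]  # freeze in place
            step = rng_noise.normal(0.0, walk_sigma, size=(n, dim))
            walkers = ~solid
            nxt = cur[walkers] + step[walkers]
            # reflect at the box walls
            for ax in range(dim):
                lo = 0.0 if ax else 0.0
                hi = box[ax]
                nxt[:, ax] = np.abs(nxt[:, ax] - lo) + lo
                over = nxt[:, ax] > hi
                nxt[over, ax] = 2 * hi - nxt[over, ax]
                np.clip(nxt[:, ax], lo, hi, out=nxt[:, ax])
            cur[walkers] = nxt
        jitter = rng_noise.normal(0.0, jitter_sigma, size=(n, dim)) if jitter_sigma > 0 else 0.0
        frame = cur.copy()
        frame[solid] = cur_anchor[solid] + (jitter[solid] if jitter_sigma > 0 else 0.0)
        pos[:, t, :] = frame
        labels[:, t] = (~solid).astype(int)

    traj = ParticleTrajectory(positions=pos, box=box, periodic=np.zeros(dim, dtype=bool),
                              dt_sample=dt_sample)
    return traj, labels


def gen_wave_toy(n_particles: int = 400, box: tuple[float, ...] = (100.0, 50.0),
                 band_width: float = 15.0, wave_speed: float = 1.0,
                 v_coherent: float = 1.0, v_jitter: float = 0.1,
                 n_frames: int = 100, seed: int = 0,
                 dt_sample: float = 1.0) -> tuple[ParticleTrajectory, np.ndarray]:
    """A coherent velocity band sweeping through a quasi-static particle field.

    Particles keep fixed (uniform random) positions; the band
    x ∈ [wave_speed·t, wave_speed·t + band_width) (wrapped) assigns its
    members velocity (v_coherent, 0, ...) plus Gaussian jitter, everyone
    else isotropic jitter only.  Returns the trajectory (with velocities)
    and a boolean (N, T) in-band label array.
    """
    box_arr = np.asarray(box, dtype=float)
    dim = box_arr.size
    if band_width <= 0 or band_width >= box_arr[0]:
        raise ValueError("band_width must lie in (0, box extent along x)")
    if n_particles < 1 or n_frames < 1:
        raise ValueError("need at least one particle and one frame")
    ss_pos, ss_noise = np.random.SeedSequence(seed).spawn(2)
    rng_pos = np.random.default_rng(ss_pos)
    rng_noise = np.random.default_rng(ss_noise)

    base = rng_pos.random((n_particles, dim)) * box_arr
    pos = np.repeat(base[:, None, :], n_frames, axis=1)

    t_idx = np.arange(n_frames)
    x0 = (wave_speed * t_idx) % box_arr[0]                      # (T,)
    rel = (base[:, None, 0] - x0[None, :]) % box_arr[0]         # (N, T)
    in_band = rel < band_width

    vel = rng_noise.normal(0.0, max(v_jitter, 0.0), size=(n_particles, n_frames, dim)) \
        if v_jitter > 0 else np.zeros((n_particles, n_frames, dim))
    vel[:, :, 0] += in_band * v_coherent

    traj = ParticleTrajectory(positions=pos, box=box_arr,
                              periodic=np.ones(dim, dtype=bool),
                              dt_sample=dt_sample, velocities=vel)
    return traj, in_band


def gen_frustrated_pair(n_series: int = 80, n_frames: int = 1500, seed: int = 0,
                        chain: MarkovSpec | None = None,
                        noise_factor: float = 2.0,
                        ) -> tuple[SignalEnsemble, SignalEnsemble, np.ndarray]:
    """Bivariate fixture exhibiting frustrated information.

    Dimension 1 is a three-state signal in which a short-lived minor
    (middle) state is clearly resolvable.  Dimension 2 is driven by the
    same state path but carries only the two dominant states, blurred by
    emission noise of sigma = ``noise_factor`` × (separation between the
    minor state and its nearest dominant neighbour).  Combining the two
    dimensions degrades the detectability of the minor state relative to
    dimension 1 alone.
    """
    chain = chain or three_state_chain()
    e1, labels = gen_state_ensemble(chain, n_series, n_frames, seed)
    means1 = np.array([s.mean[0] for s in chain.states])
    order = np.argsort(chain.stationary_distribution())
    minor = order[0]
    dominant = [k for k in range(chain.n_states) if k != minor]
    sep = min(abs(means1[minor] - means1[k]) for k in dominant)
    sigma2 = noise_factor * sep
    # dimension 2: minor state emits like its nearest dominant neighbour
    means2 = means1.copy()
    nearest = min(dominant, key=lambda k: abs(means1[minor] - means1[k]))
    means2[minor] = means1[nearest]
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[2])
    vals2 = means2[labels] + sigma2 * rng.standard_normal(labels.shape)
    e2 = SignalEnsemble(values=vals2, dt_sample=e1.dt_sample, name="dominant_noisy")
    return e1, e2, labels
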