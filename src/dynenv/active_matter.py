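"""Physics-based descriptors for tracked active-matter particles.

Two per-particle, per-frame scalars used for dense 2D colloidal rollers:

* ``d_min`` — distance to the closest other particle, a proxy for the
  local particle density;
* ``phi`` — polar order parameter: the mean cosine between a particle's
  velocity and those of its neighbors within a cutoff r_c,

      phi_i = (1 / n_c^i) * sum_j  v_i . v_j / (|v_i| |v_j|),

  with j running over the n_c^i neighbors of i (the particle itself is
  excluded — self-inclusion would bias phi toward +1).  phi lies in
  [-1, 1]; particles with no neighbor or zero speed have no defined
  value and are marked NaN (they are never classified downstream).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from ._neighbors import neighbor_lists, pairwise_distance_matrix
from .datatypes import ParticleTrajectory, SignalEnsemble

__all__ = ["AlignmentParams", "d_min", "phi", "finite_difference_velocities"]


@dataclass
class AlignmentParams:
    """r_c: neighbor cutoff (length units; 15 pixels for tracked rollers).
    undefined_policy: 'nan' marks undefined samples as missing."""

    r_c: float = 15.0
    undefined_policy: str = "nan"

    def __post_init__(self) -> None:
        if self.r_c <= 0:
            raise ValueError("r_c must be positive")
        if self.undefined_policy != "nan":
            raise ValueError("only the 'nan' undefined policy is supported")


def d_min(traj: ParticleTrajectory) -> SignalEnsemble:
    """Minimum neighbor distance per particle per frame (periodic-aware)."""
    n, t = traj.n_particles, traj.n_frames
    out = np.full((n, t), np.nan)
    for frame in range(t):
        pts = traj.frame(frame)
        if n < 2:
            continue
        if traj.periodic.all():
            tree = cKDTree(pts % traj.box, boxsize=traj.box)
            dist, _ = tree.query(pts % traj.box, k=2)
            out[:, frame] = dist[:, 1]
        elif not traj.periodic.any():
            tree = cKDTree(pts)
            dist, _ = tree.query(pts, k=2)
            out[:, frame] = dist[:, 1]
        else:
            dm = pairwise_distance_matrix(pts, traj.box, traj.periodic)
            np.fill_diagonal(dm, np.inf)
            out[:, frame] = dm.min(axis=1)
    return SignalEnsemble(values=out, dt_sample=traj.dt_sample, name="d_min")


def phi(traj: ParticleTrajectory, params: AlignmentParams | None = None) -> SignalEnsemble:
    """Local velocity alignment per particle per frame (NaN where undefined)."""
    if traj.velocities is None:
        raise ValueError("phi requires a trajectory with velocities")
    params = params or AlignmentParams()
    n, t = traj.n_particles, traj.n_frames
    out = np.full((n, t), np.nan)
    for frame in range(t):
        pts = traj.frame(frame)
        vel = traj.velocities[:, frame, :]
        speed = np.linalg.norm(vel, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = vel / speed[:, None]
        lists = neighbor_lists(pts, params.r_c, traj.box, traj.periodic)
        for i in range(n):
            js = lists[i]
            if js.size == 0 or speed[i] == 0.0:
                continue
            js = js[speed[js] > 0.0]
            if js.size == 0:
                continue
            out[i, frame] = float(np.mean(unit[js] @ unit[i]))
    return SignalEnsemble(values=out, dt_sample=traj.dt_sample, name="phi")


def finite_difference_velocities(traj: ParticleTrajectory, stride: int = 1) -> ParticleTrajectory:
    """Attach forward-difference velocities (length/frame) to a trajectory
    that was tracked without them; the last ``stride`` frames reuse the
    final difference so shapes stay aligned."""
    if stride < 1 or stride >= traj.n_frames:
        raise ValueError("stride must lie in [1, n_frames)")
    pos = traj.positions
    vel = np.empty_like(pos)
    diff = (pos[:, stride:, :] - pos[:, :-stride, :]) / stride
    for ax in np.nonzero(traj.periodic)[0]:
        diff[..., ax] -= traj.box[ax] * np.round(diff[..., ax] / traj.box[ax])
    vel[:, :-stride, :] = diff
    vel[:, -stride:, :] = diff[:, -1:, :]
    return ParticleTrajectory(positions=pos.copy(), box=traj.box.copy(),
                              periodic=traj.periodic.copy(), dt_sample=traj.dt_sample,
                              velocities=vel, species=traj.species)
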