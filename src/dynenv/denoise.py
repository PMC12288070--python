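"""Spatial denoising: neighborhood averaging of per-particle signals.

Each particle's value (scalar or descriptor vector) is replaced by the
unweighted mean of its own value and those of its neighbors within a
cutoff at the same frame.  This trades single-particle noise for a small
amount of spatial smoothing and produces the "_dn" descriptor variants.
Temporal smoothing is deliberately out of scope.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ._neighbors import neighbor_lists
from .datatypes import DescriptorSeries, ParticleTrajectory, SignalEnsemble

__all__ = ["SpatialDenoiser", "spatial_average"]


class SpatialDenoiser(TransformerMixin, BaseEstimator):
    """Transformer averaging each particle's signal with its instantaneous
    neighbors.  ``fit`` binds the trajectory that supplies the geometry;
    ``transform`` then accepts any aligned series."""

    def __init__(self, cutoff: float = 10.0) -> None:
        self.cutoff = cutoff

    def fit(self, X: ParticleTrajectory, y=None) -> "SpatialDenoiser":
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if not isinstance(X, ParticleTrajectory):
            raise TypeError("fit expects a ParticleTrajectory")
        self.traj_ = X
        # neighbor lists per frame, self prepended so the mean always
        # includes the particle's own value
        self.groups_ = []
        for t in range(X.n_frames):
            lists = neighbor_lists(X.frame(t), self.cutoff, X.box, X.periodic)
            self.groups_.append([np.concatenate(([i], js)) for i, js in enumerate(lists)])
        return self

    def transform(self, X: SignalEnsemble | DescriptorSeries):
        if not hasattr(self, "groups_"):
            raise RuntimeError("SpatialDenoiser must be fit on a trajectory first")
        traj = self.traj_
        vals = X.values
        if vals.shape[0] != traj.n_particles or vals.shape[1] != traj.n_frames:
            raise ValueError("series and trajectory are misaligned on (particle, frame)")
        out = np.empty_like(vals)
        for t in range(traj.n_frames):
            for i, grp in enumerate(self.groups_[t]):
                out[i, t] = np.mean(vals[grp, t], axis=0)
        if isinstance(X, DescriptorSeries):
            return X.with_values(out, provenance="denoised")
        return SignalEnsemble(values=out, dt_sample=X.dt_sample, name=f"{X.name}_dn")


def spatial_average(series: SignalEnsemble | DescriptorSeries,
                    traj: ParticleTrajectory, cutoff: float):
    """Functional wrapper over :class:`SpatialDenoiser`."""
    return SpatialDenoiser(cutoff=cutoff).fit(traj).transform(series)
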