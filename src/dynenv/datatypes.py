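"""Core data containers shared by all pipeline stages.

Time is kept in *frames* everywhere inside the package; ``dt_sample``
(the physical time between stored frames) is only applied when numbers
cross an I/O boundary or when Δt values are reported in time units.
This prevents unit drift when trajectories are resampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np


def n_frames(total_time: float, dt_sample: float) -> int:
    """Number of stored frames for a trajectory of ``total_time`` sampled
    every ``dt_sample`` (same units)."""
    if dt_sample <= 0 or total_time <= 0:
        raise ValueError("total_time and dt_sample must be positive")
    return int(round(total_time / dt_sample))


@dataclass
class ParticleTrajectory:
    """Positions (and optional velocities) of N particles over T frames.

    positions : (N, T, dim) array, Cartesian, origin at the box corner.
    velocities : optional (N, T, dim) array in length/frame.
    box : (dim,) box edge lengths (orthorhombic).
    periodic : (dim,) bool flags; periodic coordinates are wrapped into
        [0, box) on construction.
    dt_sample : physical time per frame (native unit of the source data).
    """

    positions: np.ndarray
    box: np.ndarray
    periodic: np.ndarray
    dt_sample: float = 1.0
    velocities: np.ndarray | None = None
    species: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3:
            raise ValueError("positions must have shape (N, T, dim)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        dim = self.positions.shape[2]
        self.box = np.asarray(self.box, dtype=float).reshape(dim)
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be positive")
        self.periodic = np.asarray(self.periodic, dtype=bool).reshape(dim)
        if self.dt_sample <= 0:
            raise ValueError("dt_sample must be positive")
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != self.positions.shape:
                raise ValueError("velocities must match positions in shape")
        for ax in np.nonzero(self.periodic)[0]:
            self.positions[..., ax] %= self.box[ax]

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    @property
    def dim(self) -> int:
        return self.positions.shape[2]

    @property
    def total_time(self) -> float:
        return self.n_frames * self.dt_sample

    def frame(self, t: int) -> np.ndarray:
        """Positions of all particles at frame ``t`` as (N, dim)."""
        return self.positions[:, t, :]

    def resample(self, stride: int) -> "ParticleTrajectory":
        """Keep frames 0, stride, 2·stride, ...; dt_sample scales by stride."""
        if stride < 1:
            raise ValueError("stride must be >= 1")
        if stride >= self.n_frames:
            raise ValueError("stride must be smaller than the number of frames")
        vel = None if self.velocities is None else self.velocities[:, ::stride, :]
        return ParticleTrajectory(
            positions=self.positions[:, ::stride, :].copy(),
            box=self.box.copy(),
            periodic=self.periodic.copy(),
            dt_sample=self.dt_sample * stride,
            velocities=None if vel is None else vel.copy(),
            species=self.species,
        )


@dataclass
class SignalEnsemble:
    """N univariate or d-variate time-series of length T.

    values : (N, T) for univariate, (N, T, d) for multivariate signals.
    NaN marks undefined samples (e.g. ϕ of an isolated particle); such
    samples are never classified by the clustering.
    """

    values: np.ndarray
    dt_sample: float = 1.0
    name: str = "signal"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim not in (2, 3):
            raise ValueError("values must have shape (N, T) or (N, T, d)")
        if self.dt_sample <= 0:
            raise ValueError("dt_sample must be positive")

    @property
    def n_series(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def n_dims(self) -> int:
        return 1 if self.values.ndim == 2 else self.values.shape[2]

    def resample(self, stride: int) -> "SignalEnsemble":
        if stride < 1:
            raise ValueError("stride must be >= 1")
        if stride >= self.n_frames:
            raise ValueError("stride must be smaller than the number of frames")
        return SignalEnsemble(
            values=self.values[:, ::stride].copy(),
            dt_sample=self.dt_sample * stride,
            name=self.name,
        )


def combine(*ensembles: SignalEnsemble, name: str = "combined") -> SignalEnsemble:
    """Stack univariate ensembles into one multivariate ensemble (N, T, d)."""
    if len(ensembles) < 2:
        raise ValueError("need at least two ensembles to combine")
    shape = ensembles[0].values.shape
    dt = ensembles[0].dt_sample
    for e in ensembles[1:]:
        if e.values.shape != shape or e.values.ndim != 2:
            raise ValueError("combine expects univariate ensembles of equal shape")
        if not np.isclose(e.dt_sample, dt):
            raise ValueError("combine expects matching dt_sample")
    return SignalEnsemble(
        values=np.stack([e.values for e in ensembles], axis=-1),
        dt_sample=dt,
        name=name,
    )


@dataclass
class DescriptorSeries:
    """Per-particle, per-frame descriptor vectors with component metadata.

    values : (N, T, D) array.
    components : length-D list of (n, n', l) tuples describing each column
        (empty for non-SOAP descriptors).
    provenance : "raw" or "denoised".
    """

    values: np.ndarray
    components: list[tuple[int, int, int]] = field(default_factory=list)
    provenance: str = "raw"
    dt_sample: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must have shape (N, T, D)")
        if self.components and len(self.components) != self.values.shape[2]:
            raise ValueError("component metadata length must equal D")

    @property
    def n_particles(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def n_components(self) -> int:
        return self.values.shape[2]

    def extract_component(self, index: int) -> SignalEnsemble:
        """Univariate ensemble of one raw descriptor component."""
        if not 0 <= index < self.n_components:
            raise ValueError(f"component index {index} out of range [0, {self.n_components})")
        suffix = "_dn" if self.provenance == "denoised" else ""
        return SignalEnsemble(
            values=self.values[:, :, index].copy(),
            dt_sample=self.dt_sample,
            name=f"component_{index}{suffix}",
        )

    def with_values(self, values: np.ndarray, provenance: str | None = None) -> "DescriptorSeries":
        return replace(
            self,
            values=values,
            provenance=self.provenance if provenance is None else provenance,
        )
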