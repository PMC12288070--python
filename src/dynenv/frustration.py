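"""Frustrated-information diagnostics.

Combining two signal dimensions can *lose* information relative to the
better of the two alone: relevant variation in one dimension acts as
noise in the other, and short-lived states that one dimension resolves
drop below the population filter in the joint analysis.  The loss is
quantified cluster-count-wise on a shared Δt grid:

    gap(Δt)       = max(n1, n2) - n12
    info_loss(Δt) = max(gap, 0)

Also here: detection windows (the Δt ranges over which at least k states
are resolved), trajectory/ensemble resampling, and the sampling-
frequency scan that compares detection windows in *absolute time*
across resamplings of the same data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import ParticleTrajectory, SignalEnsemble, combine
from .onion import DeltaTScan, default_grid, delta_t_scan

__all__ = ["FrustrationCurve", "DetectionWindow", "frustration_gap",
           "detection_window", "resample", "sampling_scan",
           "self_combination_control"]


@dataclass
class FrustrationCurve:
    delta_t: np.ndarray
    n1: np.ndarray
    n2: np.ndarray
    n12: np.ndarray
    gap_raw: np.ndarray       # max(n1, n2) - n12, sign kept
    info_loss: np.ndarray     # clamped at 0: the "gray area"
    dt_sample: float = 1.0

    @property
    def delta_t_time(self) -> np.ndarray:
        return self.delta_t * self.dt_sample


@dataclass
class DetectionWindow:
    """Maximal Δt intervals (on the scan grid) where n_states >= k."""

    k: int
    intervals_frames: list[tuple[int, int]]
    intervals_time: list[tuple[float, float]]

    @property
    def upper_edge_time(self) -> float | None:
        """Largest Δt (time units) at which the target count is resolved."""
        return self.intervals_time[-1][1] if self.intervals_time else None


def frustration_gap(scan1: DeltaTScan, scan2: DeltaTScan,
                    scan12: DeltaTScan) -> FrustrationCurve:
    """Elementwise information-loss curve of a bivariate clustering versus
    the better of its two univariate components (identical Δt grids)."""
    if not (np.array_equal(scan1.delta_t, scan2.delta_t)
            and np.array_equal(scan1.delta_t, scan12.delta_t)):
        raise ValueError("the three scans must share one Δt grid")
    best = np.maximum(scan1.n_states, scan2.n_states)
    gap = best - scan12.n_states
    return FrustrationCurve(delta_t=scan1.delta_t.copy(), n1=scan1.n_states.copy(),
                            n2=scan2.n_states.copy(), n12=scan12.n_states.copy(),
                            gap_raw=gap, info_loss=np.maximum(gap, 0),
                            dt_sample=scan1.dt_sample)


def detection_window(scan: DeltaTScan, k: int) -> DetectionWindow:
    """Maximal grid intervals with n_states >= k (no interpolation — the
    window edges are grid points)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    hit = scan.n_states >= k
    frames: list[tuple[int, int]] = []
    start = None
    for i, h in enumerate(hit):
        if h and start is None:
            start = i
        elif not h and start is not None:
            frames.append((int(scan.delta_t[start]), int(scan.delta_t[i - 1])))
            start = None
    if start is not None:
        frames.append((int(scan.delta_t[start]), int(scan.delta_t[-1])))
    times = [(a * scan.dt_sample, b * scan.dt_sample) for a, b in frames]
    return DetectionWindow(k=k, intervals_frames=frames, intervals_time=times)


def resample(data: SignalEnsemble | ParticleTrajectory, stride: int):
    """Keep frames 0, stride, 2·stride, ...; dt_sample scales by stride."""
    return data.resample(stride)


def sampling_scan(ensemble: SignalEnsemble, strides: list[int], k: int,
                  n_grid: int = 30, **onion_kwargs) -> dict[int, DetectionWindow]:
    """Detection window of the k-state regime for each resampling stride,
    reported in absolute time so windows are comparable across strides."""
    out: dict[int, DetectionWindow] = {}
    for stride in strides:
        if stride < 1:
            raise ValueError("strides must be >= 1")
        sub = ensemble if stride == 1 else ensemble.resample(stride)
        scan = delta_t_scan(sub, grid=default_grid(sub.n_frames, n_grid), **onion_kwargs)
        out[stride] = detection_window(scan, k)
    return out


def self_combination_control(ensemble: SignalEnsemble,
                             grid: np.ndarray | None = None,
                             **onion_kwargs) -> FrustrationCurve:
    """Frustration curve of an ensemble combined with an exact copy of
    itself; a faithful bivariate pipeline loses nothing here."""
    if ensemble.values.ndim != 2:
        raise ValueError("control expects a univariate ensemble")
    grid = default_grid(ensemble.n_frames) if grid is None else np.asarray(grid, dtype=int)
    scan1 = delta_t_scan(ensemble, grid=grid, **onion_kwargs)
    both = combine(ensemble, ensemble, name=f"{ensemble.name}x2")
    scan12 = delta_t_scan(both, grid=grid, **onion_kwargs)
    return frustration_gap(scan1, scan1, scan12)
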