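"""Variance-based views of a descriptor dataset.

Covariance PCA on pooled (particle x frame) rows — the ergodic pooling
under which "the PC1 time-series" is well defined — plus per-component
variance ranking split into the spherical (l = 0) and non-spherical
(l > 0) families.  Leading variance is *quantity* of information, not
necessarily quality; the ranking exists so that low-variance components
can be pulled out and clustered on their own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .datatypes import DescriptorSeries, SignalEnsemble
from .soap import spherical_mask

__all__ = ["VarianceReport", "pca", "pca_series", "component_variances",
           "extract_component"]


@dataclass
class VarianceReport:
    """Explained-variance accounting for one dataset."""

    component_variances: np.ndarray        # per raw component (descriptor units^2)
    explained_variance_ratio: np.ndarray   # per PC, sums to 1
    cumulative: np.ndarray                 # non-decreasing, ends at 1
    ranking: np.ndarray                    # raw component indices, descending variance
    spherical: np.ndarray | None = None    # True where the raw component has l = 0

    def top_components(self, k: int, family: str | None = None) -> np.ndarray:
        """Indices of the k highest-variance raw components, optionally
        restricted to the 'spherical' (l=0) or 'nonspherical' family."""
        idx = self.ranking
        if family is not None:
            if self.spherical is None:
                raise ValueError("no family metadata on this report")
            want = self.spherical if family == "spherical" else ~self.spherical
            idx = idx[want[idx]]
        return idx[:k]


def _sign_fix(components: np.ndarray) -> np.ndarray:
    """Make each loading vector's largest-magnitude entry positive; PCA
    signs are otherwise arbitrary and would break reproducibility."""
    out = components.copy()
    for i, row in enumerate(out):
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            out[i] = -row
    return out


def pca(rows: np.ndarray, k: int, standardize: bool = False
        ) -> tuple[np.ndarray, np.ndarray, VarianceReport]:
    """Covariance PCA of pooled descriptor rows.

    Returns (scores (M, k), loadings (k, D), report).  All D explained-
    variance ratios are reported regardless of k.  ``standardize``
    switches to correlation PCA (z-scored columns).
    """
    rows = np.asarray(rows, dtype=float)
    if rows.ndim != 2:
        raise ValueError("rows must be a 2D (samples x components) array")
    m, d = rows.shape
    if m < 2:
        raise ValueError("need at least 2 rows for PCA")
    if not 1 <= k <= d:
        raise ValueError(f"k must lie in 1..{d}")
    work = rows
    if standardize:
        std = rows.std(axis=0, ddof=1)
        work = (rows - rows.mean(axis=0)) / np.where(std > 0, std, 1.0)
    est = PCA(n_components=d, svd_solver="full")
    scores = est.fit_transform(work)
    loadings = _sign_fix(est.components_)
    # re-apply the sign fix to the scores
    flips = np.sign(np.sum(loadings * est.components_, axis=1))
    scores = scores * flips
    ratio = est.explained_variance_ratio_
    comp_var = work.var(axis=0, ddof=1)
    report = VarianceReport(
        component_variances=comp_var,
        explained_variance_ratio=ratio,
        cumulative=np.cumsum(ratio),
        ranking=np.argsort(comp_var)[::-1],
    )
    return scores[:, :k], loadings[:k], report


def pca_series(series: DescriptorSeries, k: int, standardize: bool = False
               ) -> tuple[list[SignalEnsemble], VarianceReport]:
    """PCA of a descriptor series; scores reshaped back to per-particle
    time-series, one univariate ensemble per principal component."""
    n, t, d = series.values.shape
    scores, _, report = pca(series.values.reshape(n * t, d), k, standardize=standardize)
    suffix = "_dn" if series.provenance == "denoised" else ""
    ensembles = [
        SignalEnsemble(values=scores[:, i].reshape(n, t), dt_sample=series.dt_sample,
                       name=f"PC{i + 1}{suffix}")
        for i in range(k)
    ]
    if series.components:
        n_max = max(c[0] for c in series.components)
        l_max = max(c[2] for c in series.components)
        report.spherical = spherical_mask(n_max, l_max)
    return ensembles, report


def component_variances(series: DescriptorSeries) -> VarianceReport:
    """Variance of each raw component over all (particle, frame) samples,
    ranked descending, with the l = 0 / l > 0 family split when the
    series carries SOAP component metadata."""
    n, t, d = series.values.shape
    rows = series.values.reshape(n * t, d)
    var = rows.var(axis=0, ddof=1) if n * t > 1 else np.zeros(d)
    total = var.sum()
    ratio = var / total if total > 0 else np.zeros(d)
    order = np.argsort(var)[::-1]
    spherical = None
    if series.components:
        n_max = max(c[0] for c in series.components)
        l_max = max(c[2] for c in series.components)
        spherical = spherical_mask(n_max, l_max)
    return VarianceReport(component_variances=var,
                          explained_variance_ratio=ratio[order],
                          cumulative=np.cumsum(ratio[order]),
                          ranking=order, spherical=spherical)


def extract_component(series: DescriptorSeries, index: int) -> SignalEnsemble:
    """The univariate (N, T) ensemble of one raw descriptor component."""
    return series.extract_component(index)
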