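"""Fiber orientation distribution (FOD) histograms and uniformity testing.

Angles are fiber-axis directions in degrees on [0, 180), 0 degrees being the
tension (image x) axis, counterclockwise positive.  Histograms carry an
effective sample size ``n_effective`` used by the chi-square uniformity test;
for weighted data this is the Kish effective n, ``(sum w)^2 / sum(w^2)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
from scipy import stats

from .exceptions import FiberwebError

__all__ = ["FODHistogram", "aggregate_fod", "uniformity_test", "UniformityResult"]


def kish_ess(weights) -> float:
    """Kish effective sample size of a weight vector."""
    w = np.asarray(weights, dtype=float)
    s = w.sum()
    if s <= 0:
        return 0.0
    return float(s * s / np.square(w).sum())


@dataclass(frozen=True)
class FODHistogram:
    """Normalized angular density over [0, 180) degrees.

    ``density`` sums to 1 over contiguous bins delimited by ``bin_edges``
    (length ``len(density) + 1``); ``n_effective`` is the weight total
    expressed as an effective number of independent orientation samples.
    """

    bin_edges: np.ndarray
    density: np.ndarray
    n_effective: float

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        dens = np.asarray(self.density, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "density", dens)
        if edges.ndim != 1 or dens.ndim != 1 or edges.size != dens.size + 1:
            raise FiberwebError("bin_edges must have len(density) + 1 entries")
        if np.any(np.diff(edges) <= 0):
            raise FiberwebError("bin edges must be strictly increasing")
        if np.any(dens < 0):
            raise FiberwebError("densities must be nonnegative")
        if dens.sum() > 0 and not np.isclose(dens.sum(), 1.0, atol=1e-9):
            raise FiberwebError(f"densities must sum to 1 (got {dens.sum()})")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @classmethod
    def from_angles(
        cls, angles_deg, weights=None, bins: int = 180
    ) -> "FODHistogram":
        """Histogram fiber-axis angles (degrees, folded into [0, 180))."""
        ang = np.mod(np.asarray(angles_deg, dtype=float), 180.0)
        if ang.size == 0:
            raise FiberwebError("no angles to histogram")
        w = None if weights is None else np.asarray(weights, dtype=float)
        counts, edges = np.histogram(ang, bins=bins, range=(0.0, 180.0), weights=w)
        total = counts.sum()
        if total <= 0:
            raise FiberwebError("zero total weight")
        n_eff = float(ang.size) if w is None else kish_ess(w)
        return cls(bin_edges=edges, density=counts / total, n_effective=n_eff)

    def to_csv(self, path) -> None:
        """Export as ``angle_deg,density`` rows (bin centers)."""
        with open(path, "w") as fh:
            fh.write(f"# n_effective: {self.n_effective!r}\n")
            fh.write("angle_deg,density\n")
            for c, d in zip(self.bin_centers, self.density):
                fh.write(f"{float(c)!r},{float(d)!r}\n")


def aggregate_fod(histograms: Iterable[FODHistogram]) -> FODHistogram:
    """Pool FOD histograms from several fields of view.

    Densities are averaged with ``n_effective`` weights and renormalized;
    effective sample sizes add.  All inputs must share one binning.
    """
    hists = list(histograms)
    if not hists:
        raise FiberwebError("nothing to aggregate")
    edges = hists[0].bin_edges
    for h in hists[1:]:
        if h.bin_edges.shape != edges.shape or not np.allclose(h.bin_edges, edges):
            raise FiberwebError("histograms have mismatched binning")
    weights = np.array([h.n_effective for h in hists], dtype=float)
    if weights.sum() <= 0:
        weights = np.ones(len(hists))
    dens = np.average([h.density for h in hists], axis=0, weights=weights)
    dens = dens / dens.sum()
    return FODHistogram(
        bin_edges=edges,
        density=dens,
        n_effective=float(sum(h.n_effective for h in hists)),
    )


class UniformityResult(NamedTuple):
    statistic: float
    pvalue: float
    dof: int


def uniformity_test(
    h: FODHistogram, n_effective: float | None = None
) -> UniformityResult:
    """Pearson chi-square goodness of fit against the uniform angular density.

    The expected per-bin mass is proportional to bin width (1/180 per degree).
    ``n_effective`` overrides the histogram's stored effective sample size —
    supply a fiber-level value when the histogram was built from pixel data,
    where pixels along one straight fiber are fully correlated.
    """
    n = float(h.n_effective if n_effective is None else n_effective)
    if not n > 0:
        raise FiberwebError("effective sample size must be > 0")
    widths = np.diff(h.bin_edges)
    expected_frac = widths / widths.sum()
    observed = n * h.density
    expected = n * expected_frac
    stat = float(np.sum((observed - expected) ** 2 / expected))
    dof = h.density.size - 1
    p = float(stats.chi2.sf(stat, dof))
    return UniformityResult(statistic=stat, pvalue=p, dof=dof)
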