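"""Stochastic RVE fiber-network generator and virtual uniaxial tensile test.

The generator realizes the idealized planar web behind the closed-form model:
``Nf`` straight fibers with i.i.d. uniform orientations on [0, pi), centers
i.i.d. uniform on the L x L square, and the arithmetic length progression
``l_i = i * 2L/Nf`` randomly assigned to fibers.  Nominal lengths are kept for
volume accounting even where a fiber overhangs the RVE boundary, so porosity
closure ``L^2 T (1 - P) = pi r^2 sum(l_i)`` holds by construction.

The virtual tensile test is a force-summation estimator (no fiber-fiber
bonding or contact): participating fibers are those that (a) survive an
independent thinning with probability ``tau = W/L`` — the areal-fraction
argument for the specimen cut — and (b) lie in the symmetric orientation band
``min(alpha, pi - alpha) <= theta = arctan(W/L)``.  Summing their axial force
components and dividing by the specimen cross-section ``W*T`` gives an
unbiased Monte Carlo estimate of the closed-form membrane stress.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

from . import model
from .exceptions import FiberwebError, OverDenseNetworkError
from .fod import FODHistogram

__all__ = [
    "FiberSegment",
    "RVENetwork",
    "generate_network",
    "network_porosity",
    "cut_specimen",
    "virtual_tensile_test",
    "fod_of_network",
    "save_network",
    "load_network",
]


@dataclass(frozen=True)
class FiberSegment:
    """One straight fiber: center (mm), axis angle (rad, [0, pi)), length and
    radius (mm)."""

    x: float
    y: float
    alpha: float
    length: float
    radius: float

    def __post_init__(self) -> None:
        if not (0 <= self.alpha < math.pi):
            raise FiberwebError("alpha must lie in [0, pi)")
        if not (self.length > 0 and self.radius > 0):
            raise FiberwebError("length and radius must be > 0")


@dataclass
class RVENetwork:
    """Explicit planar fiber network in an L x L x T volume.

    Per-fiber state is stored as parallel arrays (``x``, ``y``, ``alpha``,
    ``length`` plus the thinning variates ``strip_u`` that make specimen cuts
    deterministic functions of the network); ``segments`` iterates
    :class:`FiberSegment` views.
    """

    L: float
    T: float
    r: float  # common fiber radius, mm
    seed: int
    x: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    alpha: np.ndarray = field(repr=False)
    length: np.ndarray = field(repr=False)
    strip_u: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        n = len(self.x)
        for name in ("y", "alpha", "length", "strip_u"):
            if len(getattr(self, name)) != n:
                raise FiberwebError("per-fiber arrays must share one length")
        if n == 0:
            raise FiberwebError("a network needs at least one fiber")
        if self.realized_P < 0:
            raise OverDenseNetworkError(
                f"fiber volume exceeds RVE volume (P = {self.realized_P:.3g})"
            )

    @property
    def n_fibers(self) -> int:
        return int(len(self.x))

    @property
    def fiber_volume(self) -> float:
        """Total nominal fiber volume pi r^2 sum(l_i), mm^3."""
        return math.pi * self.r * self.r * float(self.length.sum())

    @property
    def realized_P(self) -> float:
        return 1.0 - self.fiber_volume / (self.L * self.L * self.T)

    @property
    def segments(self) -> Iterator[FiberSegment]:
        for i in range(self.n_fibers):
            yield FiberSegment(
                x=float(self.x[i]),
                y=float(self.y[i]),
                alpha=float(self.alpha[i]),
                length=float(self.length[i]),
                radius=self.r,
            )


def generate_network(
    L: float,
    T: float,
    r: float,
    P: float,
    seed: int,
    n_fibers: int | None = None,
) -> RVENetwork:
    """Sample one RVE network realization.

    ``r`` in mm.  The fiber count defaults to the porosity-closure value of
    :func:`fiberweb.model.fiber_count`; ``n_fibers`` overrides it (useful for
    scaled-down study networks).  A single seed feeds four named sub-streams
    (orientations, length permutation, centers, specimen thinning), so equal
    seeds give byte-identical networks.
    """
    if n_fibers is None:
        Nf = model.fiber_count(L, T, P, r)
    else:
        Nf = int(n_fibers)
        if Nf < 1:
            raise FiberwebError("n_fibers must be >= 1")
    if Nf < 2:
        raise FiberwebError("need at least 2 fibers for a meaningful network")
    ss = np.random.SeedSequence(int(seed))
    s_alpha, s_perm, s_centers, s_strip = ss.spawn(4)
    alpha = np.random.default_rng(s_alpha).uniform(0.0, math.pi, Nf)
    lengths = model.fiber_lengths(Nf, L)
    lengths = np.random.default_rng(s_perm).permutation(lengths)
    centers = np.random.default_rng(s_centers).uniform(0.0, L, size=(2, Nf))
    strip_u = np.random.default_rng(s_strip).uniform(0.0, 1.0, Nf)
    return RVENetwork(
        L=L,
        T=T,
        r=r,
        seed=int(seed),
        x=centers[0],
        y=centers[1],
        alpha=alpha,
        length=lengths,
        strip_u=strip_u,
    )


def network_porosity(network: RVENetwork) -> float:
    """Porosity from the realized volume bookkeeping:
    ``P = 1 - pi r^2 sum(l_i) / (L^2 T)``."""
    P = network.realized_P
    if P < 0:
        raise OverDenseNetworkError(f"over-dense network (P = {P:.3g})")
    return P


def cut_specimen(
    network: RVENetwork, W: float, geometric: bool = False
) -> np.ndarray:
    """Indices of fibers participating in a specimen of width ``W``.

    Membership combines (a) the specimen-strip cut — by default the
    pre-sampled independent thinning with probability ``tau = W/L`` that
    realizes the areal-fraction argument; with ``geometric=True`` a literal
    centered strip ``|y - L/2| <= W/2`` on fiber centers — and (b) the
    orientation band ``min(alpha, pi - alpha) <= arctan(W/L)``.  Deterministic
    given the network.
    """
    if not (0 < W <= network.L):
        raise FiberwebError(f"W must satisfy 0 < W <= L, got {W}")
    tau = W / network.L
    if geometric:
        in_strip = np.abs(network.y - network.L / 2.0) <= W / 2.0
    else:
        in_strip = network.strip_u < tau
    theta = math.atan(tau)
    folded = np.minimum(network.alpha, math.pi - network.alpha)
    in_band = folded <= theta
    return np.nonzero(in_strip & in_band)[0]


def virtual_tensile_test(
    network: RVENetwork, W: float, sigma_f: float, geometric: bool = False
) -> float:
    """Monte Carlo membrane stress (MPa): sum of participating fibers' axial
    force components ``sigma_f * pi r^2 * cos^2(alpha)`` over the specimen
    cross-section ``W * T``.

    The estimator is unbiased for the closed-form
    :func:`fiberweb.model.membrane_stress` at the network's realized porosity
    (up to the neglected single-fiber cross-section term, relative order
    ``1/Nf``).
    """
    idx = cut_specimen(network, W, geometric=geometric)
    if idx.size == 0:
        warnings.warn("no participating fibers; returning 0 stress", stacklevel=2)
        return 0.0
    forces = model.fiber_axial_force(sigma_f, network.r, network.alpha[idx])
    return float(forces.sum() / (W * network.T))


def fod_of_network(network: RVENetwork, bins: int = 180) -> FODHistogram:
    """Length-weighted angular histogram of the network's fiber axes."""
    angles_deg = np.degrees(network.alpha)
    return FODHistogram.from_angles(angles_deg, weights=network.length, bins=bins)


# ---------------------------------------------------------------------------
# serialization (plain text, one fiber per row)
# ---------------------------------------------------------------------------

_COLUMNS = "x_mm,y_mm,alpha_rad,length_mm,radius_mm,strip_u"


def save_network(network: RVENetwork, path) -> None:
    """Write the network as delimited text with metadata comment lines."""
    with open(path, "w") as fh:
        fh.write(f"# L_mm: {network.L!r}\n")
        fh.write(f"# T_mm: {network.T!r}\n")
        fh.write(f"# seed: {network.seed}\n")
        fh.write(f"# realized_P: {network.realized_P!r}\n")
        fh.write(_COLUMNS + "\n")
        for i in range(network.n_fibers):
            fh.write(
                f"{float(network.x[i])!r},{float(network.y[i])!r},"
                f"{float(network.alpha[i])!r},{float(network.length[i])!r},"
                f"{float(network.r)!r},{float(network.strip_u[i])!r}\n"
            )


def load_network(path) -> RVENetwork:
    """Read a network written by :func:`save_network`."""
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
            elif line[0].isalpha():
                if line != _COLUMNS:
                    raise FiberwebError(f"unexpected header {line!r} in {path}")
            else:
                rows.append([float(v) for v in line.split(",")])
    if not rows:
        raise FiberwebError(f"no fibers in {path}")
    arr = np.array(rows, dtype=float)
    return RVENetwork(
        L=float(meta["L_mm"]),
        T=float(meta["T_mm"]),
        r=float(arr[0, 4]),
        seed=int(meta["seed"]),
        x=arr[:, 0],
        y=arr[:, 1],
        alpha=arr[:, 2],
        length=arr[:, 3],
        strip_u=arr[:, 5],
    )
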