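"""Closed-form RVE constitutive relations for planar random fiber networks.

The model idealizes an electrospun nonwoven membrane as a square representative
volume element (RVE) of side ``L`` and thickness ``T`` filled with ``Nf``
straight, unbonded fibers of common radius ``r``.  Fiber axis angles follow the
uniform orientation density ``psi(alpha) = 1/pi`` on ``[0, pi)`` and fiber
lengths form the arithmetic progression ``l_i = i * (2L/Nf)``, so that the
total fiber volume ``pi r^2 * sum(l_i)`` fills the solid fraction ``(1 - P)``
of the RVE volume ``L^2 T`` (``P`` is the porosity).

Under uniaxial tension only fibers that bridge the cross-section of a specimen
of width ``W`` resist load; a fiber at angle ``alpha`` contributes the axial
force component ``sigma_f * pi r^2 * cos^2(alpha)``.  Averaging over the
orientation band ``|alpha| <= theta = arctan(k)``, ``k = W/L``, gives the
engineering membrane stress

    sigma = (1 - P) * (sin(theta) cos(theta) + theta) / pi * sigma_f

which is linear in the single-fiber stress ``sigma_f`` and therefore exactly
invertible for ``k > 0``.  Membrane and fiber strains are related through the
in-plane contraction coefficient ``nu_xy`` (transverse over axial strain, the
nonwoven analog of a Poisson ratio, frequently > 1 for fiber mats):

    eps_f = eps * (cos^2(alpha) - nu_xy sin^2(alpha))
          = eps * (1 - nu_xy k^2) / (1 + k^2)      at alpha = arctan(k).

Units: lengths in mm (radii accepted in nm at API boundaries and converted),
stresses in MPa, masses in g, densities in g/cm^3.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence, Union

import numpy as np

from .exceptions import (
    DegenerateGeometryError,
    FiberwebError,
    InconsistentMeasurementError,
    NonInvertibleError,
)

__all__ = [
    "MembraneGeometry",
    "PorosityRecord",
    "FiberPopulation",
    "nm_to_mm",
    "mm_to_nm",
    "porosity_from_mass",
    "fiber_count",
    "fiber_lengths",
    "specimen_fraction",
    "fiber_axial_force",
    "orientation_factor",
    "orientation_factor_from_angle",
    "membrane_stress",
    "fiber_stress_from_membrane",
    "fiber_strain",
    "fiber_strain_specimen",
    "contraction_coefficient",
    "transform_membrane_curve",
    "parametric_stress_surface",
]

NM_PER_MM = 1.0e6


def nm_to_mm(x):
    """Convert nanometers to millimeters (scalar or array)."""
    return np.multiply(x, 1.0 / NM_PER_MM)


def mm_to_nm(x):
    """Convert millimeters to nanometers (scalar or array)."""
    return np.multiply(x, NM_PER_MM)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MembraneGeometry:
    """RVE/specimen geometry.

    Parameters
    ----------
    L : float
        RVE (gauge) side length, mm.
    W : float
        Specimen width, mm.
    T : float
        Membrane thickness, mm.
    """

    L: float
    W: float
    T: float

    def __post_init__(self) -> None:
        for name in ("L", "W", "T"):
            if not getattr(self, name) > 0:
                raise FiberwebError(f"geometry dimension {name} must be > 0")
        if self.k > 1:
            warnings.warn(
                f"width-to-length ratio k = {self.k:.3g} > 1: the specimen is "
                "wider than the RVE it is cut from; formulas remain finite "
                "but the derivation assumes W <= L",
                stacklevel=2,
            )

    @property
    def k(self) -> float:
        """Width-to-length ratio W/L (dimensionless)."""
        return self.W / self.L

    @property
    def theta(self) -> float:
        """Orientation cutoff angle arctan(k), radians."""
        return math.atan(self.k)


@dataclass(frozen=True)
class PorosityRecord:
    """Gravimetric porosity measurement.

    ``M1`` is the mass of a fully compacted (zero-porosity) specimen of the
    same outer dimensions, ``M2`` the measured specimen mass, ``rho`` the
    solid fiber material density.  ``P = (M1 - M2) / M1``.
    """

    P: float
    M1: float
    M2: float
    rho: float

    def __post_init__(self) -> None:
        if not 0 <= self.P < 1:
            raise FiberwebError(f"porosity P = {self.P} outside [0, 1)")
        if self.M2 > self.M1:
            raise InconsistentMeasurementError(
                f"measured mass M2 = {self.M2} exceeds compacted mass M1 = {self.M1}"
            )


@dataclass(frozen=True)
class FiberPopulation:
    """Fiber inventory of one RVE: radius, count, length progression, volumes.

    ``lengths`` is the arithmetic progression ``l_i = i * delta_l`` with
    ``delta_l = 2L/Nf`` and ``l_Nf = 2L``; its sum is ``L * (Nf + 1)``, which
    closes the volume bookkeeping ``V_mu * (1 - P) = Vf = pi r^2 * sum(l_i)``.
    ``psi`` is the (uniform) orientation density value ``1/pi``.
    """

    r: float  # mm
    Nf: int
    lengths: np.ndarray = field(repr=False)
    delta_l: float
    Vf: float  # mm^3
    V_mu: float  # mm^3
    psi: float = 1.0 / math.pi

    @classmethod
    def from_geometry(
        cls, L: float, T: float, P: float, r_nm: float
    ) -> "FiberPopulation":
        """Build the population implied by an RVE of side ``L`` (mm), thickness
        ``T`` (mm), porosity ``P`` and fiber radius ``r_nm`` (nanometers)."""
        r = nm_to_mm(float(r_nm))
        Nf = fiber_count(L, T, P, r)
        lengths = fiber_lengths(Nf, L)
        Vf = math.pi * r * r * float(lengths.sum())
        return cls(
            r=r, Nf=Nf, lengths=lengths, delta_l=2.0 * L / Nf, Vf=Vf, V_mu=L * L * T
        )


# ---------------------------------------------------------------------------
# scalar building blocks
# ---------------------------------------------------------------------------


def porosity_from_mass(
    M2: float, L: float, W: float, T: float, rho: float
) -> float:
    """Porosity from the gravimetric method.

    ``M1 = L*W*T*rho`` (mm^3 converted to cm^3) is the mass of a fully dense
    specimen of the same size; ``P = (M1 - M2)/M1``.

    Parameters are in g (``M2``), mm (``L``, ``W``, ``T``) and g/cm^3
    (``rho``).
    """
    for name, v in (("M2", M2), ("L", L), ("W", W), ("T", T), ("rho", rho)):
        if not v > 0:
            raise FiberwebError(f"{name} must be > 0, got {v}")
    M1 = (L * W * T) * 1.0e-3 * rho  # mm^3 -> cm^3
    if M2 > M1 * (1 + 1e-12):
        raise InconsistentMeasurementError(
            f"measured mass {M2} g exceeds fully dense mass {M1} g"
        )
    return max(0.0, (M1 - M2) / M1)


def fiber_count(L: float, T: float, P: float, r: float) -> int:
    """Number of fibers in the RVE implied by porosity closure.

    From ``L^2 T (1-P) = pi r^2 sum(l_i)`` and ``sum(l_i) = L (Nf + 1)``:

        Nf = L*T*(1-P) / (pi r^2) - 1

    rounded half-away-from-zero to the nearest integer.  ``r`` in mm.
    """
    if not (0 <= P < 1):
        raise FiberwebError(f"porosity P = {P} outside [0, 1)")
    if not (L > 0 and T > 0 and r > 0):
        raise FiberwebError("L, T and r must all be > 0")
    exact = L * T * (1.0 - P) / (math.pi * r * r) - 1.0
    Nf = math.floor(exact + 0.5)
    if Nf < 1:
        raise DegenerateGeometryError(
            f"geometry admits {exact:.3g} fibers (< 1): fiber cross-section "
            "exhausts the solid volume budget"
        )
    return Nf


def fiber_lengths(Nf: int, L: float) -> np.ndarray:
    """Arithmetic length progression ``l_i = i * (2L/Nf)``, i = 1..Nf.

    The shortest fiber equals the tolerance ``delta_l = 2L/Nf``, the longest
    ``2L`` (the RVE diagonal-scale bound), and the sum is ``L * (Nf + 1)``.
    """
    if Nf < 1:
        raise FiberwebError(f"Nf must be >= 1, got {Nf}")
    if not L > 0:
        raise FiberwebError(f"L must be > 0, got {L}")
    return np.arange(1, Nf + 1, dtype=float) * (2.0 * L / Nf)


def specimen_fraction(W: float, L: float) -> float:
    """Fraction tau = W/L of RVE fibers whose anchoring cross-section falls
    inside a specimen of width ``W`` (areal-fraction argument)."""
    if not (W > 0 and L > 0):
        raise FiberwebError("W and L must be > 0")
    return W / L


def fiber_axial_force(sigma_f, r, alpha):
    """Axial force component of one fiber at angle ``alpha`` to the tension
    axis: ``F22 = sigma_f * pi r^2 * cos^2(alpha)`` (MPa * mm^2 = N)."""
    return sigma_f * math.pi * np.square(r) * np.square(np.cos(alpha))


# ---------------------------------------------------------------------------
# membrane <-> fiber stress
# ---------------------------------------------------------------------------


def orientation_factor_from_angle(theta):
    """Orientation average ``(sin(theta) cos(theta) + theta) / pi``."""
    theta = np.asarray(theta, dtype=float)
    out = (np.sin(theta) * np.cos(theta) + theta) / math.pi
    return out[()] if out.ndim == 0 else out


def orientation_factor(k):
    """Orientation average expressed directly in ``k``:

        (k + (1 + k^2) arctan k) / (pi (1 + k^2))

    Algebraically identical to :func:`orientation_factor_from_angle` at
    ``theta = arctan(k)``.
    """
    k = np.asarray(k, dtype=float)
    k2 = 1.0 + np.square(k)
    out = (k + k2 * np.arctan(k)) / (math.pi * k2)
    return out[()] if out.ndim == 0 else out


def _check_P_k(P, k) -> None:
    P = np.asarray(P, dtype=float)
    k = np.asarray(k, dtype=float)
    if np.any(P < 0) or np.any(P >= 1):
        raise FiberwebError("porosity P must lie in [0, 1)")
    if np.any(k < 0):
        raise FiberwebError("width-to-length ratio k must be >= 0")


def membrane_stress(
    sigma_f,
    P,
    k,
    *,
    exact: bool = False,
    L: float | None = None,
    T: float | None = None,
    r: float | None = None,
    calibration: float = 1.0,
):
    """Engineering membrane stress produced by single-fiber stress ``sigma_f``.

        sigma = (1 - P) * (sin(theta) cos(theta) + theta) / pi * sigma_f

    with ``theta = arctan(k)``.  ``k = 0`` gives exactly 0 (no fiber bridges a
    zero-width specimen); ``k -> inf`` approaches the upper bound
    ``(1 - P) * sigma_f / 2``.

    ``exact=True`` retains the single-fiber cross-section term normally
    neglected against the membrane cross-section, replacing the solidity
    ``(1 - P)`` by ``(1 - P) - pi r^2 / (L T)`` (requires ``L``, ``T``, ``r``
    in mm).  ``calibration`` is an optional user-supplied multiplicative
    constant (default 1, i.e. the uncalibrated model).
    """
    _check_P_k(P, k)
    solidity = 1.0 - np.asarray(P, dtype=float)
    if exact:
        if L is None or T is None or r is None:
            raise FiberwebError("exact mode requires L, T and r (mm)")
        solidity = solidity - math.pi * r * r / (L * T)
    out = calibration * solidity * orientation_factor(k) * np.asarray(
        sigma_f, dtype=float
    )
    out = np.asarray(out)
    return out[()] if out.ndim == 0 else out


def fiber_stress_from_membrane(
    sigma,
    P,
    k,
    *,
    exact: bool = False,
    L: float | None = None,
    T: float | None = None,
    r: float | None = None,
    calibration: float = 1.0,
):
    """Single-fiber stress inferred from membrane stress (exact algebraic
    inverse of :func:`membrane_stress`; requires ``k > 0``)."""
    _check_P_k(P, k)
    if np.any(np.asarray(k, dtype=float) == 0):
        raise NonInvertibleError(
            "k = 0 maps every fiber stress to zero membrane stress and cannot "
            "be inverted"
        )
    scale = membrane_stress(
        1.0, P, k, exact=exact, L=L, T=T, r=r, calibration=calibration
    )
    out = np.asarray(sigma, dtype=float) / scale
    out = np.asarray(out)
    return out[()] if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# strain mapping
# ---------------------------------------------------------------------------


def fiber_strain(eps, alpha, nu_xy):
    """Strain of a fiber at angle ``alpha`` when the web strains by ``eps``
    axially while contracting transversely with coefficient ``nu_xy``:

        eps_f = eps * (cos^2(alpha) - nu_xy * sin^2(alpha))
    """
    c2 = np.square(np.cos(alpha))
    out = np.asarray(eps, dtype=float) * (c2 - np.asarray(nu_xy) * (1.0 - c2))
    out = np.asarray(out)
    return out[()] if out.ndim == 0 else out


def fiber_strain_specimen(eps, k, nu_xy):
    """Strain of the cutoff-angle fiber (``alpha = arctan k``):

        eps_f = (1 - nu_xy k^2) / (1 + k^2) * eps

    Identical to :func:`fiber_strain` evaluated at ``alpha = arctan(k)``.
    """
    k2 = np.square(np.asarray(k, dtype=float))
    out = (1.0 - np.asarray(nu_xy) * k2) / (1.0 + k2) * np.asarray(eps, dtype=float)
    out = np.asarray(out)
    return out[()] if out.ndim == 0 else out


def contraction_coefficient(eps_x, eps_y):
    """In-plane contraction coefficient ``nu_xy = eps_x / eps_y``.

    Both strains are entered as positive magnitudes (transverse contraction
    positive); values above 1 are physical for fiber mats.
    """
    eps_y = np.asarray(eps_y, dtype=float)
    if np.any(eps_y == 0):
        raise FiberwebError("axial strain eps_y must be nonzero")
    out = np.asarray(eps_x, dtype=float) / eps_y
    out = np.asarray(out)
    return out[()] if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# curve-level operations
# ---------------------------------------------------------------------------

NuProfile = Union[float, Callable[[np.ndarray], np.ndarray]]


def _nu_at(nu_profile: NuProfile, eps: np.ndarray) -> np.ndarray:
    if callable(nu_profile):
        return np.asarray(nu_profile(eps), dtype=float)
    return np.full_like(np.asarray(eps, dtype=float), float(nu_profile))


def transform_membrane_curve(curve, P: float, k: float, nu_profile: NuProfile):
    """Map a membrane stress-strain record point-by-point to the implied
    single-fiber record: strains through :func:`fiber_strain_specimen` with
    ``nu_xy`` evaluated at each axial strain, stresses through
    :func:`fiber_stress_from_membrane`.

    The output strain axis remains strictly increasing whenever
    ``1 - nu_xy k^2 > 0`` throughout; a violation raises
    :class:`CurveValidationError`.
    """
    from .curves import StressStrainCurve  # local import: avoids cycle
    from .exceptions import CurveValidationError

    eps = np.asarray(curve.strain, dtype=float)
    sig = np.asarray(curve.stress, dtype=float)
    if np.any(np.diff(eps) <= 0):
        raise CurveValidationError("membrane curve strain must be strictly increasing")
    nu = _nu_at(nu_profile, eps)
    eps_f = fiber_strain_specimen(eps, k, nu)
    sig_f = fiber_stress_from_membrane(sig, P, k)
    if np.any(np.diff(eps_f) <= 0):
        raise CurveValidationError(
            "fiber strain axis is non-increasing: 1 - nu_xy * k^2 changes sign "
            "over the strain range"
        )
    return StressStrainCurve(strain=eps_f, stress=sig_f, rate=curve.rate)


def parametric_stress_surface(
    P_values: Sequence[float], k_values: Sequence[float], sigma_f: float = 400.0
) -> np.ndarray:
    """Membrane stress over a (porosity, width-to-length ratio) grid at fixed
    single-fiber stress (default 400 MPa).  Element ``[i, j]`` is
    ``membrane_stress(sigma_f, P_values[i], k_values[j])``; the surface is
    strictly decreasing along P and nondecreasing along k."""
    P = np.asarray(list(P_values), dtype=float)
    k = np.asarray(list(k_values), dtype=float)
    if P.size == 0 or k.size == 0:
        raise FiberwebError("P_values and k_values must be nonempty")
    return membrane_stress(sigma_f, P[:, None], k[None, :])
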