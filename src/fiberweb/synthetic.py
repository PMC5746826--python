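"""Synthetic study data: membrane curves, diameter draws, micrograph fields.

Defaults encode the study conditions of the silk-fibroin/polycaprolactone
(SF/PCL) electrospun system the model targets: mean fiber diameter 272 nm with
coefficient of variation 29.4 % (lognormal), membranes of porosity P = 0.75
tested at width-to-length ratio k = 0.125 (gauge 40 mm x width 5 mm,
thickness 0.11 mm), strain rate 0.01 1/s, and membrane tensile descriptors of
Table-2 scale: yield 4.11 MPa at strain 0.049, post-yield slope 2.60 MPa,
break strain 0.543.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import model
from .curves import ContractionProfile, StressStrainCurve, TensileSummary
from .exceptions import FiberwebError
from .imaging import measure_diameters, render_network
from .network import RVENetwork

__all__ = [
    "STUDY",
    "bilinear_membrane_curve",
    "lognormal_diameters",
    "fiber_field",
    "diameter_micrograph_study",
    "study_contraction_profile",
]


@dataclass(frozen=True)
class StudyConditions:
    """Reference experimental conditions used as generator defaults."""

    diameter_mean_nm: float = 272.0
    diameter_cv: float = 0.294
    porosity: float = 0.75
    k: float = 0.125
    L_mm: float = 40.0
    W_mm: float = 5.0
    T_mm: float = 0.11
    radius_nm: float = 136.0
    strain_rate: float = 0.01
    yield_strain: float = 0.049
    yield_stress: float = 4.11
    post_yield_slope: float = 2.60
    break_strain: float = 0.543


STUDY = StudyConditions()


def bilinear_membrane_curve(
    yield_strain: float = STUDY.yield_strain,
    yield_stress: float = STUDY.yield_stress,
    post_yield_slope: float = STUDY.post_yield_slope,
    break_strain: float = STUDY.break_strain,
    n_points: int = 120,
    noise_sd_frac: float = 0.0,
    seed: int | None = None,
    rate: float = STUDY.strain_rate,
) -> tuple[StressStrainCurve, TensileSummary]:
    """Two-segment (elastic/post-yield) membrane curve and its true summary.

    The elastic segment runs from the origin to the yield knee (slope
    ``yield_stress / yield_strain``); the post-yield segment continues with
    ``post_yield_slope`` to ``break_strain``.  The knee is included as a data
    point.  Note that a single bilinear curve cannot carry an elastic modulus
    different from the yield secant, so the returned true summary derives
    ``E`` and the break stress from the curve geometry.

    ``noise_sd_frac`` adds seeded multiplicative Gaussian noise of that
    relative standard deviation to the stresses (the first point stays 0).
    """
    if not (0 < yield_strain < break_strain):
        raise FiberwebError("need 0 < yield_strain < break_strain")
    E = yield_stress / yield_strain
    break_stress = yield_stress + post_yield_slope * (break_strain - yield_strain)
    n_pre = max(5, int(round(n_points * yield_strain / break_strain)) + 3)
    n_post = max(5, n_points - n_pre)
    eps = np.concatenate(
        [
            np.linspace(0.0, yield_strain, n_pre),
            np.linspace(yield_strain, break_strain, n_post + 1)[1:],
        ]
    )
    sig = np.where(
        eps <= yield_strain,
        E * eps,
        yield_stress + post_yield_slope * (eps - yield_strain),
    )
    if noise_sd_frac > 0:
        rng = np.random.default_rng(seed)
        sig = sig * (1.0 + noise_sd_frac * rng.standard_normal(sig.size))
        sig[0] = 0.0
    truth = TensileSummary(
        E=E,
        yield_stress=yield_stress,
        yield_strain=yield_strain,
        post_yield_slope=post_yield_slope,
        break_stress=break_stress,
        break_strain=break_strain,
        yield_method="generator",
    )
    return StressStrainCurve(strain=eps, stress=sig, rate=rate), truth


def lognormal_diameters(
    n: int,
    mean_nm: float = STUDY.diameter_mean_nm,
    cv: float = STUDY.diameter_cv,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw fiber diameters (nm) from a lognormal with the given arithmetic
    mean and coefficient of variation."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean_nm) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=int(n))


def fiber_field(
    n_fibers: int,
    field_mm: float,
    seed: int,
    length_factor: float = 1.4,
    radius_nm: float = STUDY.radius_nm,
) -> RVENetwork:
    """Sparse micrograph-like field: ``n_fibers`` straight fibers of equal
    length ``length_factor * field_mm`` crossing a square field of view.

    This is a synthetic stand-in for one FE-SEM frame, not a full RVE: fiber
    lengths are constant so every fiber spans the frame, and the thickness is
    chosen to keep the nominal porosity at the study value.
    """
    ss = np.random.SeedSequence(int(seed))
    s_alpha, s_centers, s_strip = ss.spawn(3)
    alpha = np.random.default_rng(s_alpha).uniform(0.0, math.pi, n_fibers)
    centers = np.random.default_rng(s_centers).uniform(0.0, field_mm, (2, n_fibers))
    strip_u = np.random.default_rng(s_strip).uniform(0.0, 1.0, n_fibers)
    lengths = np.full(n_fibers, length_factor * field_mm)
    r_mm = model.nm_to_mm(radius_nm)
    # thickness chosen so nominal porosity equals the study porosity
    T = math.pi * r_mm * r_mm * lengths.sum() / (
        field_mm * field_mm * (1.0 - STUDY.porosity)
    )
    return RVENetwork(
        L=field_mm,
        T=T,
        r=r_mm,
        seed=int(seed),
        x=centers[0],
        y=centers[1],
        alpha=alpha,
        length=lengths,
        strip_u=strip_u,
    )


def diameter_micrograph_study(
    n_fibers: int = 400,
    per_image: int = 3,
    image_px: int = 768,
    scale: float = 10.0,
    seed: int = 0,
    mean_nm: float = STUDY.diameter_mean_nm,
    cv: float = STUDY.diameter_cv,
):
    """Render ``n_fibers`` lognormal-diameter fibers across many synthetic
    micrographs and pool the image-measured diameters.

    Emulates the multi-frame characterization workflow: ``per_image`` fibers
    per field of view at ``scale`` nm/px, diameters measured per frame by
    skeleton/distance-transform analysis and pooled into one
    :class:`fiberweb.imaging.DiameterStats`.

    Returns ``(stats, true_diameters_nm)``.
    """
    from .imaging import DiameterStats  # local import keeps module API tidy

    n_images = int(math.ceil(n_fibers / per_image))
    rng = np.random.default_rng(seed)
    diameters = lognormal_diameters(n_images * per_image, mean_nm, cv, rng)
    field_mm = image_px * scale / 1.0e6
    pooled = []
    for j in range(n_images):
        net = fiber_field(per_image, field_mm, seed=int(seed) * 100003 + j)
        d = diameters[j * per_image : (j + 1) * per_image]
        img = render_network(net, scale=scale, diameters=d)
        stats = measure_diameters(img)
        pooled.append(stats.values)
    return (
        DiameterStats.from_values(np.concatenate(pooled)),
        diameters[: n_images * per_image],
    )


def study_contraction_profile(
    n_points: int = 30,
    nu_start: float = 1.65,
    nu_end: float = 2.23,
    max_strain: float = STUDY.break_strain,
) -> ContractionProfile:
    """Contraction-coefficient profile rising linearly with axial strain.

    Fiber mats contract faster than solids as fibers realign toward the
    tension axis; the default ramp (1.65 at yield-scale strains to 2.23 at
    break-scale strains) reproduces the strain mapping implied by the study's
    membrane-vs-fiber strain comparison.
    """
    axial = np.linspace(0.005, max_strain, n_points)
    nu = nu_start + (nu_end - nu_start) * (axial - axial[0]) / (
        axial[-1] - axial[0]
    )
    return ContractionProfile(axial, nu * axial, nu)
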