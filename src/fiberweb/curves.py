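"""Tensile-record containers, descriptor extraction and fiber-property prediction.

A :class:`StressStrainCurve` is an engineering stress-strain record.
:func:`summarize_curve` extracts the standard materials-testing descriptors
(elastic modulus, yield point, post-yield slope, break point);
:func:`predict_fiber_properties` pushes a membrane summary through the RVE
model to the implied single-fiber summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import model
from .exceptions import CurveValidationError, FiberwebError

__all__ = [
    "StressStrainCurve",
    "TensileSummary",
    "ContractionProfile",
    "load_curve",
    "save_curve",
    "summarize_curve",
    "contraction_profile",
    "predict_fiber_properties",
    "batch_stats",
]


@dataclass(frozen=True)
class StressStrainCurve:
    """Engineering tensile record: ``strain`` (dimensionless, strictly
    increasing) vs ``stress`` (MPa); ``rate`` is the engineering strain rate
    (1/s, metadata only)."""

    strain: np.ndarray
    stress: np.ndarray
    rate: float | None = None

    def __post_init__(self) -> None:
        strain = np.asarray(self.strain, dtype=float)
        stress = np.asarray(self.stress, dtype=float)
        object.__setattr__(self, "strain", strain)
        object.__setattr__(self, "stress", stress)
        if strain.ndim != 1 or strain.shape != stress.shape:
            raise CurveValidationError("strain and stress must be equal-length 1-D")
        if strain.size < 2:
            raise CurveValidationError("a curve needs at least two points")
        if np.any(np.diff(strain) <= 0):
            raise CurveValidationError("strain must be strictly increasing")
        if not (np.all(np.isfinite(strain)) and np.all(np.isfinite(stress))):
            raise CurveValidationError("non-finite values in curve")

    def __len__(self) -> int:
        return int(self.strain.size)


@dataclass(frozen=True)
class TensileSummary:
    """Descriptor set mirroring standard tensile-test reporting.

    ``yield_method`` records how the yield point was located ("bilinear",
    "offset", "offset->bilinear" fallback, or "linear" when the curve never
    yields and the yield fields are NaN).
    """

    E: float
    yield_stress: float
    yield_strain: float
    post_yield_slope: float
    break_stress: float
    break_strain: float
    yield_method: str = "unspecified"

    def __post_init__(self) -> None:
        if np.isfinite(self.yield_strain) and self.break_strain < self.yield_strain:
            raise FiberwebError("break_strain must be >= yield_strain")


NUMERIC_FIELDS = (
    "E",
    "yield_stress",
    "yield_strain",
    "post_yield_slope",
    "break_stress",
    "break_strain",
)


class ContractionProfile:
    """Pointwise contraction coefficient nu_xy(eps) = transverse/axial strain.

    Lookup interpolates linearly in axial strain with constant extrapolation
    beyond the measured range.
    """

    def __init__(
        self,
        axial_strain: np.ndarray,
        transverse_strain: np.ndarray,
        nu_xy: np.ndarray,
    ):
        self.axial_strain = np.asarray(axial_strain, dtype=float)
        self.transverse_strain = np.asarray(transverse_strain, dtype=float)
        self.nu_xy = np.asarray(nu_xy, dtype=float)
        if not (
            self.axial_strain.shape
            == self.transverse_strain.shape
            == self.nu_xy.shape
        ):
            raise FiberwebError("profile arrays must share one shape")
        if self.axial_strain.size == 0:
            raise FiberwebError("empty contraction profile")

    def __call__(self, eps):
        out = np.interp(np.asarray(eps, dtype=float), self.axial_strain, self.nu_xy)
        return out[()] if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def load_curve(path, dialect: str | None = None) -> StressStrainCurve:
    """Read a delimited-text tensile record.

    Expected columns ``strain, stress_MPa`` (header optional; otherwise the
    first two numeric columns are used).  Lines starting with ``#`` are
    treated as metadata comments.  ``dialect`` forces the separator
    (e.g. ``","`` or ``"\\t"``); default sniffs commas/whitespace.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"curve file not found: {path}")
    sep = dialect if dialect is not None else None
    df = pd.read_csv(path, comment="#", sep=sep, engine="python")
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "strain" in cols:
        strain = df["strain"]
        stress_col = next(
            (c for c in cols if c.startswith("stress")), None
        )
        if stress_col is None:
            raise CurveValidationError(f"no stress column in {path} (columns: {cols})")
        stress = df[stress_col]
    else:
        if df.shape[1] < 2:
            raise CurveValidationError(f"{path} needs two numeric columns")
        strain, stress = df.iloc[:, 0], df.iloc[:, 1]
    strain = pd.to_numeric(strain, errors="raise").to_numpy(dtype=float)
    stress = pd.to_numeric(stress, errors="raise").to_numpy(dtype=float)
    return StressStrainCurve(strain=strain, stress=stress)


def save_curve(curve: StressStrainCurve, path, metadata: dict | None = None) -> None:
    """Write ``strain,stress_MPa`` CSV with ``#``-prefixed metadata lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, val in (metadata or {}).items():
            fh.write(f"# {key}: {val}\n")
        fh.write("strain,stress_MPa\n")
        for e, s in zip(curve.strain, curve.stress):
            fh.write(f"{float(e)!r},{float(s)!r}\n")


# ---------------------------------------------------------------------------
# descriptor extraction
# ---------------------------------------------------------------------------


def _two_segment_fit(strain: np.ndarray, stress: np.ndarray):
    """Continuous two-segment least-squares fit with the knee at a data point.

    Model: sigma = a + b1*eps + b2*max(eps - eps_k, 0).  Returns
    (eps_k, sigma_k, slope1, slope2, rms_residual).
    """
    n = strain.size
    best = None
    for j in range(2, n - 2):
        ek = strain[j]
        X = np.column_stack(
            [np.ones(n), strain, np.maximum(strain - ek, 0.0)]
        )
        coef, *_ = np.linalg.lstsq(X, stress, rcond=None)
        resid = stress - X @ coef
        sse = float(resid @ resid)
        if best is None or sse < best[0]:
            best = (sse, ek, coef)
    sse, ek, (a, b1, b2) = best
    sigma_k = a + b1 * ek
    rms = np.sqrt(sse / n)
    return ek, sigma_k, b1, b1 + b2, rms


def summarize_curve(
    curve: StressStrainCurve,
    method: str = "auto",
    elastic_fraction: float = 0.4,
    offset: float = 0.002,
) -> TensileSummary:
    """Extract tensile descriptors from a stress-strain record.

    * elastic modulus ``E``: least-squares slope over the initial linear
      region (first ``elastic_fraction`` of the pre-yield strain range);
    * yield point: ``method="bilinear"`` takes the knee of a continuous
      two-segment least-squares fit; ``method="offset"`` intersects the
      ``offset``-strain line of slope ``E`` with the curve (falling back to
      the bilinear knee when the line never crosses); ``method="auto"``
      (default) uses the bilinear knee when its fit residual is negligible
      (i.e. the record is noiselessly bilinear), else the offset
      construction;
    * post-yield slope: least-squares slope between yield and break;
    * break point: last recorded point (engineering convention).

    A record that never departs from its initial line has no yield point: the
    yield fields are NaN and ``yield_method`` is ``"linear"``.
    """
    if method not in ("auto", "bilinear", "offset"):
        raise FiberwebError(f"unknown yield method {method!r}")
    eps = curve.strain
    sig = curve.stress
    if eps.size < 10:
        raise CurveValidationError("need >= 10 points to summarize a curve")

    scale = float(np.max(np.abs(sig))) or 1.0
    ek, sk, slope1, slope2, rms = _two_segment_fit(eps, sig)

    # entirely linear record: the two slopes coincide and a single line fits
    one_line = np.polyfit(eps, sig, 1)
    one_rms = float(np.sqrt(np.mean((np.polyval(one_line, eps) - sig) ** 2)))
    if one_rms < 1e-9 * scale or abs(slope2 - slope1) < 1e-9 * abs(slope1):
        return TensileSummary(
            E=float(one_line[0]),
            yield_stress=float("nan"),
            yield_strain=float("nan"),
            post_yield_slope=float("nan"),
            break_stress=float(sig[-1]),
            break_strain=float(eps[-1]),
            yield_method="linear",
        )

    def modulus(eps_yield: float) -> float:
        lim = elastic_fraction * eps_yield
        mask = eps <= lim
        if mask.sum() < 3:
            mask = np.zeros_like(eps, dtype=bool)
            mask[: max(3, eps.size // 10)] = True
        p = np.polyfit(eps[mask], sig[mask], 1)
        return float(p[0])

    use_bilinear = method == "bilinear" or (method == "auto" and rms < 1e-4 * scale)
    if use_bilinear:
        eps_y, sig_y = float(ek), float(sk)
        E = modulus(eps_y)
        tag = "bilinear"
    else:
        E = modulus(float(ek))  # provisional yield estimate fixes the region
        line = E * (eps - offset)
        diff = sig - line
        cross = np.nonzero((diff[:-1] > 0) & (diff[1:] <= 0))[0]
        if cross.size:
            i = cross[0]
            # linear interpolation of the sign change
            t = diff[i] / (diff[i] - diff[i + 1])
            eps_y = float(eps[i] + t * (eps[i + 1] - eps[i]))
            sig_y = float(E * (eps_y - offset))
            tag = "offset"
        else:
            eps_y, sig_y = float(ek), float(sk)
            tag = "offset->bilinear"

    post_mask = eps >= eps_y
    if post_mask.sum() >= 2:
        p = np.polyfit(eps[post_mask], sig[post_mask], 1)
        post_slope = float(p[0])
    else:
        post_slope = float("nan")

    return TensileSummary(
        E=E,
        yield_stress=sig_y,
        yield_strain=eps_y,
        post_yield_slope=post_slope,
        break_stress=float(sig[-1]),
        break_strain=float(eps[-1]),
        yield_method=tag,
    )


def contraction_profile(
    axial: Sequence[float],
    transverse: Sequence[float],
    smooth: int | None = None,
) -> ContractionProfile:
    """Pointwise nu_xy = transverse/axial with optional moving-average
    smoothing (window ``smooth`` points).  Points with zero axial strain are
    skipped with a warning."""
    axial = np.asarray(axial, dtype=float)
    transverse = np.asarray(transverse, dtype=float)
    if axial.shape != transverse.shape or axial.ndim != 1:
        raise FiberwebError("axial and transverse must be equal-length 1-D")
    if np.any(np.diff(axial) <= 0):
        raise FiberwebError("axial strain must be strictly increasing")
    keep = axial != 0
    if not np.all(keep):
        warnings.warn("dropping points with zero axial strain", stacklevel=2)
    axial, transverse = axial[keep], transverse[keep]
    nu = transverse / axial
    if smooth is not None and smooth > 1:
        nu = (
            pd.Series(nu)
            .rolling(int(smooth), center=True, min_periods=1)
            .mean()
            .to_numpy()
        )
    return ContractionProfile(axial, transverse, nu)


# ---------------------------------------------------------------------------
# prediction and batch statistics
# ---------------------------------------------------------------------------


def predict_fiber_properties(
    membrane_summary: TensileSummary,
    P: float,
    k: float,
    nu_profile,
) -> TensileSummary:
    """Map a measured membrane summary to the implied single-fiber summary.

    Stresses map through the inverse RVE relation, strains through the
    specimen strain map with ``nu_xy`` evaluated at the membrane yield and
    break strains; the fiber modulus is reported as the mapped yield stress
    over the mapped yield strain, and the post-yield slope as the secant
    between the mapped yield and break points.
    """
    ms = membrane_summary
    nu_y = float(model._nu_at(nu_profile, np.asarray(ms.yield_strain)))
    nu_b = float(model._nu_at(nu_profile, np.asarray(ms.break_strain)))
    sig_y = float(model.fiber_stress_from_membrane(ms.yield_stress, P, k))
    sig_b = float(model.fiber_stress_from_membrane(ms.break_stress, P, k))
    eps_y = float(model.fiber_strain_specimen(ms.yield_strain, k, nu_y))
    eps_b = float(model.fiber_strain_specimen(ms.break_strain, k, nu_b))
    E = sig_y / eps_y if eps_y != 0 else float("nan")
    post = (sig_b - sig_y) / (eps_b - eps_y) if eps_b != eps_y else float("nan")
    return TensileSummary(
        E=E,
        yield_stress=sig_y,
        yield_strain=eps_y,
        post_yield_slope=post,
        break_stress=sig_b,
        break_strain=eps_b,
        yield_method=ms.yield_method,
    )


def batch_stats(summaries: Iterable[TensileSummary]) -> pd.DataFrame:
    """Average/Minimum/Maximum/CV table over replicate summaries.

    CV uses the population standard deviation (divide by n), the common
    materials-testing convention.  Rows are properties, columns the four
    statistics.
    """
    summaries = list(summaries)
    if len(summaries) < 2:
        raise FiberwebError("batch statistics need at least two summaries")
    rows = {}
    for name in NUMERIC_FIELDS:
        vals = np.array([getattr(s, name) for s in summaries], dtype=float)
        mean = float(vals.mean())
        std = float(vals.std())  # population (ddof=0)
        rows[name] = {
            "Average": mean,
            "Minimum": float(vals.min()),
            "Maximum": float(vals.max()),
            "CV": std / mean if mean != 0 else float("nan"),
        }
    return pd.DataFrame(rows).T[["Average", "Minimum", "Maximum", "CV"]]
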