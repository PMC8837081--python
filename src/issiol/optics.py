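"""Double-K SRK/T vergence optics for post-LASIK IOL power calculation.

The eye is modelled as a thin spectacle lens at vertex distance ``V`` in
front of a single refracting cornea, with a thin intraocular lens (IOL) at
the estimated effective lens position (ELP, historically ``ACDest``) inside
media of refractive index ``na``.  The double-K principle separates the two
roles keratometry plays in third-generation formulas: the ELP is estimated
from the *pre*-refractive-surgery corneal power (``Kpre``, a fixed 43.86 D
population estimate when no history is available), while the vergence
calculation uses the *post*-surgery anterior radius derived from measured
keratometry (``rpost = 337.5/Kpost``).  This avoids the hyperopic surprise
caused by feeding a LASIK-flattened K into the ELP regression.

The ISS method adds a correction ``C`` (diopters, linear in the
anterior-posterior corneal radius ratio; see :mod:`issiol.cfactor`) to the
double-K predicted refraction, and inverts the same vergence equation to
obtain the IOL power that achieves a desired postoperative refraction.

Sign conventions: refractions are spherical equivalents at the spectacle
plane with myopia negative; all lengths in millimetres, powers in diopters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping

__all__ = [
    "OpticalConstants",
    "SrktInternals",
    "EyeBiometry",
    "LensConstants",
    "ElpIntermediates",
    "RefractionResult",
    "InvalidGeometryError",
    "keratometric_radius",
    "keratometric_power",
    "adjusted_axial_length",
    "elp_estimate",
    "predicted_refraction_double_k",
    "iss_predicted_refraction",
    "iss_iol_power",
    "select_iol_power",
]


class InvalidGeometryError(ValueError):
    """Raised when the vergence geometry degenerates (ELP at or behind retina,
    vanishing denominator, non-physical input)."""


@dataclass(frozen=True)
class OpticalConstants:
    """Physical constants of the schematic eye used by the vergence chain.

    Parameters
    ----------
    na : float
        Refractive index of the intraocular media (aqueous/vitreous), 1.336.
    nc : float
        Refractive index of the cornea used in the vergence terms, 1.333.
    nk : float
        Keratometric index relating anterior radius to clinical K readings,
        1.3375 (i.e. K = 337.5 / radius-in-mm).
    vertex_mm : float
        Spectacle vertex distance in mm, 12.
    kpre_default_d : float
        Population estimate of pre-LASIK corneal power in D, 43.86, used for
        ELP estimation when no refractive-surgery history exists.
    """

    na: float = 1.336
    nc: float = 1.333
    nk: float = 1.3375
    vertex_mm: float = 12.0
    kpre_default_d: float = 43.86

    def __post_init__(self) -> None:
        if not (1.0 < self.nc <= self.na):
            raise ValueError(f"require 1 < nc <= na, got nc={self.nc}, na={self.na}")
        if not (1.0 < self.nk < 1.4):
            raise ValueError(f"keratometric index out of range: {self.nk}")
        if self.vertex_mm <= 0:
            raise ValueError("vertex distance must be positive")
        if self.kpre_default_d <= 0:
            raise ValueError("kpre_default_d must be positive")


@dataclass(frozen=True)
class SrktInternals:
    """Coefficients of the SRK/T effective-lens-position chain.

    These are the published SRK/T regression sub-formulas: the long-eye
    axial-length correction (LCOR), computed corneal width (Cw), corneal
    height (H), and the A-constant to ACD-constant mapping.  They are
    surfaced here so every number in the ELP estimate is auditable and
    overridable from configuration.
    """

    lcor_threshold_mm: float = 24.2
    lcor_c0: float = -3.446
    lcor_c1: float = 1.715
    lcor_c2: float = -0.0237
    cw_c0: float = -5.41
    cw_c1: float = 0.58412
    cw_c2: float = 0.098
    acd_const_slope: float = 0.62467
    acd_const_intercept: float = -68.747
    offset_shift: float = -3.336
    # retinal-thickness correction of optical axial length
    lopt_intercept: float = 0.65696
    lopt_slope: float = -0.02029
    # vergence degenerates as the lens plane approaches the retina
    min_lens_retina_mm: float = 0.5


@dataclass(frozen=True)
class EyeBiometry:
    """One eye's measured inputs.

    axial_length_mm : optical axial length L (IOLMaster), mm.
    kpost_d : mean keratometry after LASIK (keratometric index 1.3375), D.
    r_anterior_mm / r_posterior_mm : mean anterior / posterior corneal radii
        of curvature over the central 3.0 mm zone (Scheimpflug), mm.
    """

    axial_length_mm: float
    kpost_d: float
    r_anterior_mm: float | None = None
    r_posterior_mm: float | None = None

    def __post_init__(self) -> None:
        if not (15.0 < self.axial_length_mm < 40.0):
            raise ValueError(
                f"axial length {self.axial_length_mm} mm outside plausible 15-40 mm"
            )
        if not (25.0 < self.kpost_d < 60.0):
            raise ValueError(f"keratometry {self.kpost_d} D outside plausible 25-60 D")
        for name in ("r_anterior_mm", "r_posterior_mm"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")

    @property
    def ap_ratio(self) -> float:
        from .cfactor import ap_ratio

        if self.r_anterior_mm is None or self.r_posterior_mm is None:
            raise ValueError("both corneal radii are required for the A-P ratio")
        return ap_ratio(self.r_anterior_mm, self.r_posterior_mm)


@dataclass(frozen=True)
class LensConstants:
    """IOL model constants: the SRK A-constant and, optionally, the labelled
    power of the implanted lens (needed to predict refraction, not to choose
    a power)."""

    a_constant: float
    implanted_power_d: float | None = None

    def __post_init__(self) -> None:
        if not (100.0 < self.a_constant < 125.0):
            raise ValueError(f"A-constant {self.a_constant} outside plausible 100-125")


@dataclass(frozen=True)
class ElpIntermediates:
    """Audit trail of the SRK/T ELP estimate (all lengths in mm)."""

    kpre_d: float
    rpre_mm: float
    lcor_mm: float
    cw_mm: float
    h_mm: float
    h_clamped: bool
    acd_const: float
    offset_mm: float
    acd_est_mm: float


@dataclass(frozen=True)
class RefractionResult:
    """Predicted spherical-equivalent refraction at the spectacle plane (D,
    myopia negative) together with the quantities the vergence chain used."""

    predicted_refraction_d: float
    lopt_mm: float
    rpost_mm: float
    c_applied_d: float
    elp: ElpIntermediates


def keratometric_radius(k_d: float, nk: float = 1.3375) -> float:
    """Convert corneal power (D) to anterior radius of curvature (mm).

    radius = 1000 * (nk - 1) / K; with the standard keratometric index this
    is the familiar 337.5 / K.
    """
    if k_d <= 0:
        raise ValueError(f"corneal power must be positive, got {k_d}")
    return 1000.0 * (nk - 1.0) / k_d


def keratometric_power(radius_mm: float, nk: float = 1.3375) -> float:
    """Exact inverse of :func:`keratometric_radius`: radius (mm) to power (D)."""
    if radius_mm <= 0:
        raise ValueError(f"radius must be positive, got {radius_mm}")
    return 1000.0 * (nk - 1.0) / radius_mm


def adjusted_axial_length(
    axial_length_mm: float, internals: SrktInternals = SrktInternals()
) -> float:
    """Retinal-thickness adjusted axial length LOPT = L + 0.65696 - 0.02029*L
    for optical-biometry measurements."""
    if axial_length_mm <= 0:
        raise ValueError("axial length must be positive")
    return (
        axial_length_mm
        + internals.lopt_intercept
        + internals.lopt_slope * axial_length_mm
    )


def elp_estimate(
    kpre_d: float,
    axial_length_mm: float,
    a_constant: float,
    constants: OpticalConstants = OpticalConstants(),
    internals: SrktInternals = SrktInternals(),
) -> ElpIntermediates:
    """SRK/T estimate of the effective lens position from Kpre, L and the
    A-constant.

    This is the double-K half of the calculation: only the pre-surgery
    corneal power enters, so the estimate is invariant to the measured
    post-LASIK keratometry.  Chain: rpre from Kpre; LCOR (identity below
    24.2 mm, quadratic above); corneal width Cw; corneal height
    H = rpre - sqrt(rpre^2 - Cw^2/4) with the radicand clamped at zero for
    extreme geometries; ACD-constant from the A-constant; ELP = H + offset.
    """
    if kpre_d <= 0:
        raise ValueError("kpre_d must be positive")
    LensConstants(a_constant)  # range check
    rpre = keratometric_radius(kpre_d, constants.nk)
    L = axial_length_mm
    if L <= internals.lcor_threshold_mm:
        lcor = L
    else:
        lcor = internals.lcor_c0 + internals.lcor_c1 * L + internals.lcor_c2 * L * L
    cw = internals.cw_c0 + internals.cw_c1 * lcor + internals.cw_c2 * kpre_d
    radicand = rpre * rpre - cw * cw / 4.0
    clamped = radicand < 0.0
    if clamped:
        warnings.warn(
            f"corneal height radicand negative (rpre={rpre:.3f} mm, Cw={cw:.3f} mm); "
            "clamping H to rpre",
            RuntimeWarning,
            stacklevel=2,
        )
        radicand = 0.0
    h = rpre - math.sqrt(radicand)
    acd_const = internals.acd_const_slope * a_constant + internals.acd_const_intercept
    offset = acd_const + internals.offset_shift
    acd_est = h + offset
    if acd_est <= 0:
        raise InvalidGeometryError(
            f"non-positive ELP estimate ({acd_est:.3f} mm) for A={a_constant}"
        )
    lopt = adjusted_axial_length(L, internals)
    if lopt - acd_est <= internals.min_lens_retina_mm:
        raise InvalidGeometryError(
            f"ELP {acd_est:.2f} mm within {internals.min_lens_retina_mm} mm of the "
            f"adjusted axial length {lopt:.2f} mm"
        )
    return ElpIntermediates(
        kpre_d=kpre_d,
        rpre_mm=rpre,
        lcor_mm=lcor,
        cw_mm=cw,
        h_mm=h,
        h_clamped=clamped,
        acd_const=acd_const,
        offset_mm=offset,
        acd_est_mm=acd_est,
    )


def _vergence_terms(
    eye: EyeBiometry,
    kpre_d: float,
    a_constant: float,
    constants: OpticalConstants,
    internals: SrktInternals,
) -> tuple[float, float, float, float, float, float, ElpIntermediates]:
    """Shared pieces of Eq.-style vergence algebra.

    Returns (r, lopt, q, t_lopt, t_acd, acd, elp) where
    t_lopt = na*r - (nc-1)*LOPT, t_acd = na*r - (nc-1)*ACD, q = LOPT - ACD.
    """
    na, nc = constants.na, constants.nc
    r = keratometric_radius(eye.kpost_d, constants.nk)
    lopt = adjusted_axial_length(eye.axial_length_mm, internals)
    elp = elp_estimate(kpre_d, eye.axial_length_mm, a_constant, constants, internals)
    acd = elp.acd_est_mm
    q = lopt - acd
    t_lopt = na * r - (nc - 1.0) * lopt
    t_acd = na * r - (nc - 1.0) * acd
    return r, lopt, q, t_lopt, t_acd, acd, elp


def predicted_refraction_double_k(
    eye: EyeBiometry,
    lens: LensConstants,
    kpre_d: float | None = None,
    constants: OpticalConstants = OpticalConstants(),
    internals: SrktInternals = SrktInternals(),
) -> RefractionResult:
    """Double-K SRK/T predicted postoperative refraction for an implanted
    power (D, spectacle plane, myopia negative).

    REF = [1000*na*(na*r - (nc-1)*LOPT) - LP*(LOPT-ACD)*(na*r - (nc-1)*ACD)]
          / [na*(V*(na*r - (nc-1)*LOPT) + LOPT*r)
             - 0.001*LP*(LOPT-ACD)*(V*(na*r - (nc-1)*ACD) + ACD*r)]

    with r = 337.5/Kpost and ACD estimated from Kpre alone.
    """
    if lens.implanted_power_d is None:
        raise ValueError("implanted_power_d is required to predict refraction")
    if kpre_d is None:
        kpre_d = constants.kpre_default_d
    lp = lens.implanted_power_d
    na, v = constants.na, constants.vertex_mm
    r, lopt, q, t_lopt, t_acd, acd, elp = _vergence_terms(
        eye, kpre_d, lens.a_constant, constants, internals
    )
    num = 1000.0 * na * t_lopt - lp * q * t_acd
    den = na * (v * t_lopt + lopt * r) - 0.001 * lp * q * (v * t_acd + acd * r)
    if abs(den) < 1e-9:
        raise InvalidGeometryError("vergence denominator vanishes")
    return RefractionResult(
        predicted_refraction_d=num / den,
        lopt_mm=lopt,
        rpost_mm=r,
        c_applied_d=0.0,
        elp=elp,
    )


def iss_predicted_refraction(
    eye: EyeBiometry,
    lens: LensConstants,
    c_factor_d: float,
    kpre_d: float | None = None,
    constants: OpticalConstants = OpticalConstants(),
    internals: SrktInternals = SrktInternals(),
) -> RefractionResult:
    """ISS predicted postoperative refraction: the double-K SRK/T prediction
    plus the C-factor correction (D)."""
    base = predicted_refraction_double_k(eye, lens, kpre_d, constants, internals)
    return replace(
        base,
        predicted_refraction_d=base.predicted_refraction_d + c_factor_d,
        c_applied_d=c_factor_d,
    )


def iss_iol_power(
    eye: EyeBiometry,
    desired_refraction_d: float,
    c_factor_d: float,
    a_constant: float,
    kpre_d: float | None = None,
    constants: OpticalConstants = OpticalConstants(),
    internals: SrktInternals = SrktInternals(),
) -> float:
    """IOL power (D, exact, unrounded) that makes the ISS predicted
    refraction equal the desired refraction DR.

    Algebraic inversion of the prediction formula at the effective target
    DX = DR - C:

    LP = [1000*na*(na*r - (nc-1)*LOPT) - DX*na*(V*(na*r-(nc-1)*LOPT) + LOPT*r)]
         / [(LOPT-ACD) * (na*r - (nc-1)*ACD - 0.001*DX*(V*(na*r-(nc-1)*ACD) + ACD*r))]
    """
    if kpre_d is None:
        kpre_d = constants.kpre_default_d
    dx = desired_refraction_d - c_factor_d
    na, v = constants.na, constants.vertex_mm
    r, lopt, q, t_lopt, t_acd, acd, _ = _vergence_terms(
        eye, kpre_d, a_constant, constants, internals
    )
    num = 1000.0 * na * t_lopt - dx * na * (v * t_lopt + lopt * r)
    den = q * (t_acd - 0.001 * dx * (v * t_acd + acd * r))
    if den <= 0:
        raise InvalidGeometryError("power-formula denominator non-positive")
    return num / den


def select_iol_power(exact_power_d: float, step_d: float = 0.5) -> float:
    """Round an exact power to the manufactured step (default 0.5 D).

    Ties (exactly halfway) round *up* to the higher power: a stronger lens
    leaves the more myopic residual, the conventional safety preference
    after myopic LASIK.
    """
    if step_d <= 0:
        raise ValueError("step must be positive")
    scaled = exact_power_d / step_d
    lower = math.floor(scaled)
    frac = scaled - lower
    if abs(frac - 0.5) < 1e-12:
        return (lower + 1) * step_d
    return round(scaled) * step_d


def constants_from_mapping(cfg: Mapping) -> tuple[OpticalConstants, SrktInternals]:
    """Build (OpticalConstants, SrktInternals) from a configuration mapping
    with optional ``optical`` and ``srkt`` sections (e.g. parsed TOML/YAML)."""
    oc = OpticalConstants(**dict(cfg.get("optical", {})))
    si = SrktInternals(**dict(cfg.get("srkt", {})))
    return oc, si
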