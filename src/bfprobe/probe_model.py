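"""Probe mechanics: stiffness from aspiration geometry, deformation, force.

A pipette-aspirated red blood cell with a bead glued to its apex acts as a
calibrated spring.  In the linear elastic regime the restoring force is
``F = k * Delta_x`` where ``Delta_x(t) = x(t) - x_0`` is the change of the
bead-centre-to-pipette-anchor distance relative to a zero-load reference
``x_0``, and the stiffness follows from micropipette-aspiration mechanics:

    k = R_p * dP * pi / (1 - r_p) /
        [ ln(4 / (r_c * r_p)) - (1 - r_p/4 - 3/8 r_p^2 + r_c^2) ]

with r_p = R_p / R_0 and r_c = R_c / R_0 the pipette and contact radii
normalized by the aspirated-cell radius.  With radii in micrometres and the
aspiration pressure dP in pascals, k comes out directly in pN/um
(1 um * Pa = 1 pN/um).  The linear relation holds for |Delta_x| below about
0.5 um; beyond that it overestimates the force and frames are flagged.

When geometry or the reference frame is missing the model degrades to
*generic* (tilde) mode: a built-in typical geometry yields an
order-of-magnitude stiffness and the course is marked uncalibrated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np

#: |Delta_x| above which the linear force-extension relation overestimates F.
LINEAR_REGIME_UM = 0.5

#: default measurement uncertainties: 0.1 um per radius (0.2 um per
#: diameter at optical resolution), 5 Pa on the manometer.
DEFAULT_SIGMA_R_UM = 0.1
DEFAULT_SIGMA_P_PA = 5.0


class ModelDomainError(ValueError):
    """Geometry outside the validity domain of the stiffness formula."""


@dataclass(frozen=True)
class ProbeGeometry:
    """Probe geometry and aspiration pressure, with measurement uncertainties.

    All radii in micrometres, pressure in pascals.
    """

    R_p: float  # pipette (inner) radius
    R_c: float  # bead-RBC contact radius
    R_0: float  # radius of the aspirated RBC under zero load
    dP: float  # aspiration pressure
    sigma_R: float = DEFAULT_SIGMA_R_UM
    sigma_P: float = DEFAULT_SIGMA_P_PA

    def __post_init__(self) -> None:
        if not self.R_c > 0:
            raise ModelDomainError(f"contact radius must be positive, got {self.R_c}")
        if not 0 < self.R_p < self.R_0:
            raise ModelDomainError(
                f"need 0 < R_p < R_0 (normalized pipette radius in (0,1)), "
                f"got R_p={self.R_p}, R_0={self.R_0}"
            )
        if not self.dP > 0:
            raise ModelDomainError(f"aspiration pressure must be positive, got {self.dP}")
        if self.sigma_R < 0 or self.sigma_P < 0:
            raise ModelDomainError("uncertainties must be non-negative")

    # normalized radii are always derived, never stored
    @property
    def r_p(self) -> float:
        return self.R_p / self.R_0

    @property
    def r_c(self) -> float:
        return self.R_c / self.R_0


#: built-in generic geometry for uncalibrated (tilde) force estimates
GENERIC_GEOMETRY = ProbeGeometry(R_p=1.0, R_c=0.75, R_0=2.5, dP=200.0)


def compute_stiffness(geom: ProbeGeometry) -> float:
    """Probe stiffness k in pN/um from aspiration geometry and pressure."""
    r_p, r_c = geom.r_p, geom.r_c
    log_term = math.log(4.0 / (r_c * r_p))
    bracket = 1.0 - 0.25 * r_p - 0.375 * r_p**2 + r_c**2
    denom = log_term - bracket
    if not denom > 0:
        raise ModelDomainError(
            f"stiffness denominator log(4/(r_c*r_p)) - (1 - r_p/4 - 3/8 r_p^2 + r_c^2) "
            f"= {log_term:.6g} - {bracket:.6g} = {denom:.6g} is not positive; "
            "geometry outside the model's validity domain"
        )
    return geom.R_p * geom.dP * math.pi / (1.0 - r_p) / denom


def compute_force(dx_um: np.ndarray, k: float) -> Tuple[np.ndarray, np.ndarray]:
    """Elementwise force F = k * Delta_x (pN) plus linear-regime flags.

    Frames with |Delta_x| > 0.5 um exceed the linear force-extension regime;
    the value is still returned (the overestimate is the best available
    number) but the frame is flagged.
    """
    if not k > 0:
        raise ValueError(f"stiffness must be positive, got {k}")
    dx = np.asarray(dx_um, dtype=np.float64)
    force = k * dx
    nonlinear = np.abs(dx) > LINEAR_REGIME_UM
    return force, nonlinear


@dataclass
class ForceCourse:
    """Calibrated (or generic) deformation and force time course."""

    frames: np.ndarray
    x_um: np.ndarray
    x0_um: float
    dx_um: np.ndarray
    k_pN_per_um: float
    F_pN: np.ndarray
    calibrated: bool
    nonlinear_flags: np.ndarray
    time_s: Optional[np.ndarray] = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "frame": self.frames,
                "time_s": self.time_s if self.time_s is not None else np.nan,
                "x_um": self.x_um,
                "dx_um": self.dx_um,
                "force_pN": self.F_pN,
                "calibrated": self.calibrated,
                "nonlinear_flag": self.nonlinear_flags.astype(int),
            }
        )


def compute_deformation(
    bead_track,
    pipette_track,
    pixel_scale: float,
    t0: Optional[int] = None,
    projected: bool = False,
):
    """Anchor-bead distance course x(t), reference x_0 and Delta_x = x - x_0.

    ``x(t)`` is the Euclidean distance between the pipette anchor and the
    bead centre times the pixel scale (um/px).  Under the axial assumption
    (bead, cell and anchor on one line) this equals the cell extension; with
    ``projected=True`` only the x-axis component is used instead.

    When ``t0`` is None or not among the tracked frames, the first processed
    frame serves as an arbitrary reference and the course is reported
    uncalibrated: Delta_x is then shifted by an unknown constant.

    Returns ``(x_um, x0_um, dx_um, calibrated)``.
    """
    if not pixel_scale > 0:
        raise ValueError(f"pixel_scale must be positive, got {pixel_scale}")
    bf = np.asarray(bead_track.frames)
    pf = np.asarray(pipette_track.frames)
    if bf.shape != pf.shape or not np.array_equal(bf, pf):
        raise ValueError("bead and pipette tracks cover different frames")
    bead_xy = np.asarray(bead_track.positions, dtype=np.float64)
    anchor_xy = np.asarray(pipette_track.positions, dtype=np.float64)
    delta = anchor_xy - bead_xy
    if projected:
        x_px = np.abs(delta[:, 0])
    else:
        x_px = np.hypot(delta[:, 0], delta[:, 1])
    x_um = x_px * pixel_scale
    calibrated = t0 is not None and int(t0) in bf
    if calibrated:
        x0 = float(x_um[np.flatnonzero(bf == int(t0))[0]])
    else:
        x0 = float(x_um[0])
    return x_um, x0, x_um - x0, calibrated


def stiffness_uncertainty(geom: ProbeGeometry) -> float:
    """First-order relative uncertainty of k, in percent.

    Independent Gaussian errors sigma_R on each of the three radii and
    sigma_P on the pressure propagate in quadrature through the stiffness
    formula; partial derivatives are taken by central finite differences
    with relative step 1e-4.  Since k is linear in dP, the pressure term is
    exactly sigma_P/dP.  For typical geometry measured off the video at
    optical resolution this comes to roughly 20%.
    """
    k0 = compute_stiffness(geom)
    total = (geom.sigma_P / geom.dP) ** 2
    for name in ("R_p", "R_c", "R_0"):
        v = getattr(geom, name)
        h = 1e-4 * v
        k_hi = compute_stiffness(replace(geom, **{name: v + h}))
        k_lo = compute_stiffness(replace(geom, **{name: v - h}))
        dk_dv = (k_hi - k_lo) / (2.0 * h)
        total += (dk_dv * geom.sigma_R / k0) ** 2
    return 100.0 * math.sqrt(total)
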