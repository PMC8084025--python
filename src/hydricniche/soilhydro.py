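"""Soil water retention: volumetric water content <-> water potential.

Hand-held soil moisture meters report volumetric water content (VWC, %),
while the water actually available to a frog is set by the soil water
potential (psi, kPa, <= 0).  The two are linked by a soil-class-specific
retention curve; this module uses the van Genuchten form

.. math::

    \\theta(\\psi) = \\theta_r + (\\theta_s - \\theta_r)
        \\left[1 + (\\alpha |\\psi|)^n\\right]^{-m}, \\qquad m = 1 - 1/n,

with theta in % VWC and alpha in kPa^-1, and its closed-form inverse.
The packaged sand and clay curves are calibrated so that the absorption
threshold of -50 kPa corresponds to 10.5% VWC in sandy soil and 27.6%
VWC in clayey soil.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError, OutOfRangeError

__all__ = [
    "RetentionCurve",
    "vwc_to_psi",
    "psi_to_vwc",
    "calibrate_alpha",
    "SAND",
    "CLAY",
    "DEFAULT_CURVES",
]


@dataclass(frozen=True)
class RetentionCurve:
    """Van Genuchten retention parameters for one soil class.

    theta_r / theta_s are residual and saturated VWC in %,
    alpha is in kPa^-1 and n (> 1) is the pore-size index.
    """

    soil_class: str
    theta_r: float
    theta_s: float
    alpha: float
    n: float

    def __post_init__(self):
        if not (0 <= self.theta_r < self.theta_s <= 100):
            raise InvalidInputError("need 0 <= theta_r < theta_s <= 100")
        if self.alpha <= 0:
            raise InvalidInputError("alpha must be positive")
        if self.n <= 1:
            raise InvalidInputError("n must exceed 1")

    @property
    def m(self) -> float:
        return 1.0 - 1.0 / self.n


def psi_to_vwc(psi, curve: RetentionCurve):
    """Volumetric water content (%) at water potential ``psi`` (kPa, <= 0)."""
    p = np.asarray(psi, dtype=float)
    if np.any(p > 0) or not np.all(np.isfinite(p)):
        raise InvalidInputError("psi must be finite and <= 0 kPa")
    s_eff = np.power(1.0 + np.power(curve.alpha * np.abs(p), curve.n), -curve.m)
    theta = curve.theta_r + (curve.theta_s - curve.theta_r) * s_eff
    return float(theta) if np.ndim(psi) == 0 else theta


def vwc_to_psi(vwc, curve: RetentionCurve):
    """Water potential (kPa, <= 0) at volumetric water content ``vwc`` (%).

    Defined for ``theta_r < vwc <= theta_s``; saturation maps to 0 kPa.
    """
    t = np.asarray(vwc, dtype=float)
    if np.any(t <= curve.theta_r) or np.any(t > curve.theta_s):
        raise OutOfRangeError(
            f"vwc must lie in ({curve.theta_r}, {curve.theta_s}] % "
            f"for soil class {curve.soil_class!r}"
        )
    s_eff = (t - curve.theta_r) / (curve.theta_s - curve.theta_r)
    psi = -np.power(np.power(s_eff, -1.0 / curve.m) - 1.0, 1.0 / curve.n) / curve.alpha
    return float(psi) if np.ndim(vwc) == 0 else psi


def calibrate_alpha(
    soil_class: str,
    theta_r: float,
    theta_s: float,
    n: float,
    anchor_vwc: float,
    anchor_psi: float,
) -> RetentionCurve:
    """Build a curve whose alpha is solved from one (VWC, psi) anchor pair.

    Given theta_r, theta_s and n, alpha has a closed form from a single
    anchor: the curve then passes exactly through (anchor_psi,
    anchor_vwc).
    """
    if not (theta_r < anchor_vwc < theta_s):
        raise InvalidInputError("anchor_vwc must lie strictly inside (theta_r, theta_s)")
    if anchor_psi >= 0:
        raise InvalidInputError("anchor_psi must be negative")
    m = 1.0 - 1.0 / n
    s_eff = (anchor_vwc - theta_r) / (theta_s - theta_r)
    alpha = (s_eff ** (-1.0 / m) - 1.0) ** (1.0 / n) / abs(anchor_psi)
    return RetentionCurve(soil_class, theta_r, theta_s, alpha, n)


#: Sandy-soil curve anchored at 10.5% VWC <-> -50 kPa.
SAND = calibrate_alpha("sand", theta_r=4.0, theta_s=40.0, n=1.6,
                       anchor_vwc=10.5, anchor_psi=-50.0)

#: Clayey-soil curve anchored at 27.6% VWC <-> -50 kPa.
CLAY = calibrate_alpha("clay", theta_r=10.0, theta_s=48.0, n=1.25,
                       anchor_vwc=27.6, anchor_psi=-50.0)

DEFAULT_CURVES = {"sand": SAND, "clay": CLAY}


def curves_from_mapping(mapping) -> dict[str, RetentionCurve]:
    """Build curves from a config mapping soil_class -> four parameters."""
    out = {}
    for name, params in mapping.items():
        out[name] = RetentionCurve(
            soil_class=name,
            theta_r=float(params["theta_r"]),
            theta_s=float(params["theta_s"]),
            alpha=float(params["alpha"]),
            n=float(params["n"]),
        )
    return out
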