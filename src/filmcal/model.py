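"""Single-target single-hit response model for radiographic film, in pixel
units.

The sensitometric (characteristic) curve of radiographic film is well
described by a saturation exponential: one ionising event per silver grain
suffices to make the grain developable, so the developed-grain fraction —
and hence the scanner pixel value — saturates with dose as

    P(D) = P0 + Ps * (1 - exp(-m * D / Ps))

where

``P0``
    background pixel value of unexposed film (fog plus base layer),
``Ps``
    saturation pixel value *above background* — the asymptotic net signal
    when every grain is developed, a proxy for grain concentration of the
    film batch,
``m``
    sensitivity slope in counts per cGy; the initial slope dP/dD at D = 0,
    which carries the energy/geometry and film-processing dependences.

Note the convention: ``Ps`` is the net saturation signal, so the total
pixel value tends to ``P0 + Ps`` at large dose.  All pixel values are
real-valued ROI averages, not integer scanner counts.

Dose inversion is the closed form

    D(P) = -(Ps / m) * ln(1 - (P - P0) / Ps),

defined for ``P0 <= P < P0 + Ps``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import BelowBackgroundError, DomainError, SaturationError

__all__ = [
    "CalibrationParams",
    "DosePoint",
    "IrradiationGeometry",
    "pixel_from_dose",
    "dose_from_pixel",
    "initial_slope",
]

# Inversion within this relative distance of saturation is refused: the
# scanner-saturation regime is outside the model's validity and the log
# would return physically meaningless huge doses.
_SATURATION_RTOL = 1e-9


@dataclass(frozen=True)
class CalibrationParams:
    """The (P0, Ps, m) triple defining one film response curve.

    Parameters
    ----------
    P0 : float
        Background pixel value (counts), >= 0.
    Ps : float
        Saturation pixel value above background (counts), > 0.
    m : float
        Sensitivity slope (counts per cGy), > 0.
    """

    P0: float
    Ps: float
    m: float

    def __post_init__(self) -> None:
        for name, value in (("P0", self.P0), ("Ps", self.Ps), ("m", self.m)):
            if not math.isfinite(value):
                raise DomainError(f"{name} must be finite, got {value!r}")
        if self.Ps <= 0:
            raise DomainError(f"Ps must be > 0, got {self.Ps}")
        if self.m <= 0:
            raise DomainError(f"m must be > 0, got {self.m}")
        if self.P0 < 0:
            raise DomainError(f"P0 must be >= 0, got {self.P0}")

    @property
    def saturation_pixel(self) -> float:
        """Total pixel value at full saturation, ``P0 + Ps``."""
        return self.P0 + self.Ps

    def as_dict(self) -> dict[str, float]:
        return {"P0": self.P0, "Ps": self.Ps, "m": self.m}


@dataclass(frozen=True)
class DosePoint:
    """A single (dose, pixel) calibration measurement."""

    dose: float
    pixel: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.dose) or self.dose < 0:
            raise DomainError(f"dose must be finite and >= 0, got {self.dose}")
        if not math.isfinite(self.pixel):
            raise DomainError(f"pixel must be finite, got {self.pixel}")


@dataclass(frozen=True)
class IrradiationGeometry:
    """Beam geometry metadata: SSD, square field size and phantom depth, cm.

    The beam quality is carried as a free-text label (``energy``, default
    6 MV photons); the model itself never interprets it.
    """

    ssd: float
    field_size: float
    depth: float
    energy: str = "6MV"

    def __post_init__(self) -> None:
        for name, value in (
            ("ssd", self.ssd),
            ("field_size", self.field_size),
            ("depth", self.depth),
        ):
            if not (math.isfinite(value) and value > 0):
                raise DomainError(f"{name} must be finite and > 0, got {value}")


def pixel_from_dose(params: CalibrationParams, dose):
    """Forward model: pixel value at ``dose`` (cGy).

    Accepts a scalar or array dose; strictly increasing in dose and bounded
    above by ``P0 + Ps``.

    Raises
    ------
    DomainError
        If any dose is negative or non-finite.
    """
    d = np.asarray(dose, dtype=float)
    if np.any(~np.isfinite(d)) or np.any(d < 0):
        raise DomainError("dose must be finite and >= 0")
    out = params.P0 + params.Ps * (-np.expm1(-params.m * d / params.Ps))
    return float(out) if np.isscalar(dose) or d.ndim == 0 else out


def dose_from_pixel(params: CalibrationParams, pixel):
    """Invert the response curve: dose (cGy) producing ``pixel``.

    Exact algebraic inverse of :func:`pixel_from_dose` on the open range
    ``P0 <= pixel < P0 + Ps``.

    Raises
    ------
    BelowBackgroundError
        If any pixel lies below the background ``P0``.
    SaturationError
        If any pixel is at or beyond saturation (within 1e-9 relative of
        ``P0 + Ps``): the dose is undefined there.
    """
    p = np.asarray(pixel, dtype=float)
    if np.any(~np.isfinite(p)):
        raise DomainError("pixel must be finite")
    net = p - params.P0
    if np.any(net < 0):
        raise BelowBackgroundError(
            f"pixel below background P0={params.P0}: dose undefined"
        )
    frac = net / params.Ps
    if np.any(frac >= 1.0 - _SATURATION_RTOL):
        raise SaturationError(
            f"pixel at or beyond saturation P0+Ps={params.saturation_pixel}: "
            "dose undefined"
        )
    out = -(params.Ps / params.m) * np.log1p(-frac)
    return float(out) if np.isscalar(pixel) or p.ndim == 0 else out


def initial_slope(params: CalibrationParams) -> float:
    """Initial slope dP/dD at zero dose (counts per cGy).

    For the saturation-exponential model this is exactly the ``m``
    parameter.
    """
    return params.m
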