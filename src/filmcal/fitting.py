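"""Calibration-curve fitting strategies.

Estimates the response-curve parameters (P0, Ps, m) from between one and
eight (dose, pixel) points.  Four strategies are provided, trading dose
points against prior knowledge of the batch:

``fit_full``
    Unconstrained least squares on all points; P0 either fixed to a
    measured background film or floated (then >= 4 points are needed).
``fit_method_i``
    Universal background *and* universal saturation value assumed known;
    only the sensitivity slope m is determined, from 1 or 2 points.
``fit_method_ii``
    Universal saturation value plus one background film; P0 comes from the
    background film, m from 1 or 2 points.
``fit_method_iii``
    One background film plus 2 or 3 points; both Ps and m are determined
    from the data.
``fit_batch_two_step``
    The batch procedure: fit every film of a batch freely, average the
    fitted Ps values (excluding the 8-field reference film, whose Ps is
    systematically low due to inter-field scatter cross-talk), then refit
    each film's m with Ps fixed to that batch-optimal value.

Exactly-determined cases (one point / one unknown, two points / two
unknowns) are solved by closed form or bracketed 1-D root finding rather
than general optimisation, so they are deterministic to machine precision.
Least-squares objectives are unweighted sums of squared pixel residuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize

from .errors import (
    ConfigError,
    DomainError,
    FitInfeasibleError,
    UnidentifiableError,
)
from .model import CalibrationParams, DosePoint, IrradiationGeometry, pixel_from_dose

__all__ = [
    "CalibrationDataset",
    "FitConfig",
    "FitResult",
    "fit_full",
    "fit_method_i",
    "fit_method_ii",
    "fit_method_iii",
    "fit_batch_two_step",
    "fit",
]

# Fitted curves whose maximum probed response fraction m*D/Ps stays below
# this never approach saturation, so Ps is not constrained by the data.
_MIN_PROBED_FRACTION = 0.02


@dataclass(frozen=True)
class CalibrationDataset:
    """Measured calibration points plus acquisition metadata.

    ``points`` are sorted by dose on construction; doses must be positive
    and distinct, and pixel values must increase with dose (film response
    is monotone).  ``background_pixel`` is the ROI mean of an unexposed
    film from the same batch, when one was scanned.
    ``is_eightfield_reference`` marks the multi-subfield reference film,
    which is excluded from batch Ps averaging.
    """

    points: tuple[DosePoint, ...]
    background_pixel: float | None = None
    geometry: IrradiationGeometry | None = None
    batch_id: str = ""
    day_id: str = ""
    is_eightfield_reference: bool = False

    def __post_init__(self) -> None:
        pts = tuple(sorted(self.points, key=lambda q: q.dose))
        if not pts:
            raise DomainError("dataset needs at least one point")
        doses = [q.dose for q in pts]
        if min(doses) <= 0:
            raise DomainError("doses must be strictly positive")
        if len(set(doses)) != len(doses):
            raise DomainError("doses must be distinct")
        pixels = [q.pixel for q in pts]
        if any(b <= a for a, b in zip(pixels, pixels[1:])):
            raise DomainError("pixel values must increase with dose")
        if self.background_pixel is not None and not math.isfinite(
            self.background_pixel
        ):
            raise DomainError("background_pixel must be finite")
        object.__setattr__(self, "points", pts)

    @property
    def doses(self) -> np.ndarray:
        return np.array([q.dose for q in self.points])

    @property
    def pixels(self) -> np.ndarray:
        return np.array([q.pixel for q in self.points])

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class FitConfig:
    """Strategy selection and numerical controls for :func:`fit`.

    ``method`` is one of ``"full"``, ``"I"``, ``"II"``, ``"III"``.
    Method I requires both universal values; Method II the universal Ps
    plus a dataset background; Method III a dataset background and >= 2
    points.
    """

    method: Literal["full", "I", "II", "III"] = "full"
    universal_P0: float | None = None
    universal_Ps: float | None = None
    tolerance: float = 1e-10
    max_iter: int = 200

    def __post_init__(self) -> None:
        if self.method not in ("full", "I", "II", "III"):
            raise ConfigError(f"unknown method {self.method!r}")
        if self.method == "I" and (
            self.universal_P0 is None or self.universal_Ps is None
        ):
            raise ConfigError("method I requires universal_P0 and universal_Ps")
        if self.method == "II" and self.universal_Ps is None:
            raise ConfigError("method II requires universal_Ps")


@dataclass(frozen=True)
class FitResult:
    """Fitted parameters with goodness-of-fit."""

    params: CalibrationParams
    method: str
    rms: float
    n_points: int
    notes: tuple[str, ...] = field(default_factory=tuple)

    def as_dict(self) -> dict:
        d = self.params.as_dict()
        d.update(method=self.method, rms=self.rms, n_points=self.n_points)
        return d


def _closed_form_m(P0: float, Ps: float, dose: float, pixel: float) -> float:
    """Slope from a single point: m = -(Ps/D) ln(1 - (P - P0)/Ps)."""
    net = pixel - P0
    if net < 0:
        raise FitInfeasibleError(
            f"pixel {pixel} below assumed background {P0}: no admissible slope"
        )
    frac = net / Ps
    if frac >= 1.0:
        raise FitInfeasibleError(
            f"pixel {pixel} at or beyond assumed saturation {P0 + Ps}"
        )
    return -(Ps / dose) * math.log1p(-frac)


def _rms(params: CalibrationParams, data: CalibrationDataset) -> float:
    res = pixel_from_dose(params, data.doses) - data.pixels
    return float(np.sqrt(np.mean(res**2)))


def _fit_m_only(
    P0: float, Ps: float, data: CalibrationDataset
) -> float:
    """Least-squares slope with P0, Ps fixed (1-D, deterministic).

    With a single point this is the closed form; otherwise a bounded
    scalar minimisation bracketed by the per-point closed-form slopes.
    """
    doses, pixels = data.doses, data.pixels
    per_point = [_closed_form_m(P0, Ps, d, p) for d, p in zip(doses, pixels)]
    if len(per_point) == 1:
        m = per_point[0]
    else:
        lo, hi = 0.5 * min(per_point), 2.0 * max(per_point)

        def sse(m: float) -> float:
            pred = P0 + Ps * (-np.expm1(-m * doses / Ps))
            return float(np.sum((pred - pixels) ** 2))

        res = optimize.minimize_scalar(
            sse, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-12 * max(per_point)},
        )
        m = float(res.x)
    if m <= 0:
        raise FitInfeasibleError("fitted slope is not positive")
    return m


def fit_method_i(
    data: CalibrationDataset, universal_P0: float, universal_Ps: float
) -> FitResult:
    """Slope-only fit with universal background and saturation values.

    One point gives the closed-form slope; two points a 1-D least-squares
    slope.  Raises :class:`FitInfeasibleError` when a pixel is outside
    (universal_P0, universal_P0 + universal_Ps).
    """
    if len(data) not in (1, 2):
        raise ConfigError("method I uses 1 or 2 dose points")
    m = _fit_m_only(universal_P0, universal_Ps, data)
    params = CalibrationParams(universal_P0, universal_Ps, m)
    return FitResult(params, "I", _rms(params, data), len(data))


def fit_method_ii(data: CalibrationDataset, universal_Ps: float) -> FitResult:
    """Slope fit with universal saturation; background from the dataset's
    unexposed film."""
    if data.background_pixel is None:
        raise ConfigError("method II requires a background film measurement")
    if len(data) not in (1, 2):
        raise ConfigError("method II uses 1 or 2 dose points")
    P0 = data.background_pixel
    m = _fit_m_only(P0, universal_Ps, data)
    params = CalibrationParams(P0, universal_Ps, m)
    return FitResult(params, "II", _rms(params, data), len(data))


def _solve_two_point(P0: float, data: CalibrationDataset) -> tuple[float, float]:
    """Exact (Ps, m) from two points with fixed background.

    Eliminating m between the two model equations leaves a monotone 1-D
    equation in Ps, solved by bracketed root finding:

        g(Ps) = Ps * (1 - (1 - y1/Ps)**(D2/D1)) - y2 = 0

    with y_i the net pixel values.  A solution with Ps, m > 0 exists iff
    the data are sub-linear (y2/y1 < D2/D1); otherwise the saturation
    model cannot pass through both points.
    """
    (d1, p1), (d2, p2) = (
        (q.dose, q.pixel) for q in data.points
    )
    y1, y2 = p1 - P0, p2 - P0
    if y1 <= 0:
        raise FitInfeasibleError("lower point does not exceed background")
    r = d2 / d1
    if y2 >= r * y1:
        # linear or super-linear data: Ps -> infinity (unidentifiable) or
        # no positive solution at all
        if math.isclose(y2, r * y1, rel_tol=1e-12):
            raise UnidentifiableError(
                "points are exactly proportional to dose: saturation not probed"
            )
        raise FitInfeasibleError(
            "points are super-linear in dose: inconsistent with saturation model"
        )

    def g(Ps: float) -> float:
        return Ps * (1.0 - (1.0 - y1 / Ps) ** r) - y2

    lo = max(y1, y2) * (1 + 1e-12)
    hi = max(y1, y2) * 2.0
    # expand until the sub-linear limit r*y1 > y2 flips the sign
    while g(hi) < 0:
        hi *= 2.0
        if hi > 1e12 * y1:
            raise UnidentifiableError("saturation value not constrained by points")
    Ps = float(optimize.brentq(g, lo, hi, xtol=1e-12 * y1, rtol=8.9e-16))
    m = _closed_form_m(P0, Ps, d1, p1)
    return Ps, m


def fit_method_iii(data: CalibrationDataset) -> FitResult:
    """Background film plus 2-3 points determine P0 (measured), Ps and m.

    Two points solve the nonlinear system exactly; three points are fit by
    least squares over (Ps, m).
    """
    if data.background_pixel is None:
        raise ConfigError("method III requires a background film measurement")
    if len(data) not in (2, 3):
        raise ConfigError("method III uses 2 or 3 dose points")
    P0 = data.background_pixel
    if len(data) == 2:
        Ps, m = _solve_two_point(P0, data)
        params = CalibrationParams(P0, Ps, m)
    else:
        params = _least_squares_fit(data, P0_fixed=P0)
    return FitResult(params, "III", _rms(params, data), len(data))


def _least_squares_fit(
    data: CalibrationDataset,
    P0_fixed: float | None,
    Ps_fixed: float | None = None,
    max_iter: int = 200,
    tolerance: float = 1e-10,
) -> CalibrationParams:
    """Bounded least squares on pixel residuals.

    Free parameters are whichever of (P0, Ps, m) are not fixed.
    Initialisation: slope from the secant through the lowest-dose net
    pixel; Ps from 1.2x the maximum net pixel (guarantees the implied
    response fraction stays below 1 at the start).
    """
    doses, pixels = data.doses, data.pixels
    P0_0 = P0_fixed if P0_fixed is not None else min(0.95 * pixels[0], pixels[0] - 1.0)
    P0_0 = max(P0_0, 0.0)
    net_max = pixels[-1] - P0_0
    if net_max <= 0:
        raise FitInfeasibleError("all pixels at or below background")
    Ps_0 = Ps_fixed if Ps_fixed is not None else 1.2 * net_max
    m_0 = max((pixels[0] - P0_0) / doses[0], 1e-6)

    free: list[str] = []
    x0: list[float] = []
    lb: list[float] = []
    ub: list[float] = []
    if P0_fixed is None:
        free.append("P0")
        x0.append(P0_0)
        lb.append(0.0)
        ub.append(float(pixels[0]))
    if Ps_fixed is None:
        free.append("Ps")
        x0.append(Ps_0)
        lb.append(1e-6)
        ub.append(np.inf)
    free.append("m")
    x0.append(m_0)
    lb.append(1e-12)
    ub.append(np.inf)

    def unpack(x: np.ndarray) -> tuple[float, float, float]:
        vals = dict(zip(free, x))
        return (
            vals.get("P0", P0_fixed if P0_fixed is not None else 0.0),
            vals.get("Ps", Ps_fixed if Ps_fixed is not None else 1.0),
            vals["m"],
        )

    def residuals(x: np.ndarray) -> np.ndarray:
        P0, Ps, m = unpack(x)
        return P0 + Ps * (-np.expm1(-m * doses / Ps)) - pixels

    sol = optimize.least_squares(
        residuals,
        x0,
        bounds=(lb, ub),
        xtol=tolerance,
        ftol=tolerance,
        gtol=None,
        max_nfev=max_iter * (len(free) + 1),
    )
    if not sol.success:
        raise FitInfeasibleError(f"least squares did not converge: {sol.message}")
    P0, Ps, m = unpack(sol.x)
    if m <= 0 or Ps <= 0:
        raise FitInfeasibleError("fitted parameters violate positivity")
    if m * doses[-1] / Ps < _MIN_PROBED_FRACTION:
        raise UnidentifiableError(
            "response stays within {:.1%} of saturation over the dose range: "
            "Ps is not constrained by these points".format(_MIN_PROBED_FRACTION)
        )
    return CalibrationParams(P0, Ps, m)


def fit_full(
    data: CalibrationDataset,
    float_background: bool = False,
    max_iter: int = 200,
    tolerance: float = 1e-10,
) -> FitResult:
    """Unrestricted least-squares fit of the response curve.

    By default P0 is fixed to the measured background film (>= 3 points
    needed); with ``float_background=True`` (or no background measured)
    P0 is a free parameter and >= 4 points are required.
    """
    P0_fixed: float | None
    if float_background or data.background_pixel is None:
        if len(data) < 4:
            raise ConfigError("full fit with free P0 needs >= 4 points")
        P0_fixed = None
    else:
        if len(data) < 3:
            raise ConfigError("full fit needs >= 3 points")
        P0_fixed = data.background_pixel
    params = _least_squares_fit(
        data, P0_fixed=P0_fixed, max_iter=max_iter, tolerance=tolerance
    )
    return FitResult(params, "full", _rms(params, data), len(data))


def fit(data: CalibrationDataset, config: FitConfig) -> FitResult:
    """Dispatch to the strategy selected in ``config``."""
    if config.method == "full":
        return fit_full(
            data, max_iter=config.max_iter, tolerance=config.tolerance
        )
    if config.method == "I":
        return fit_method_i(data, config.universal_P0, config.universal_Ps)
    if config.method == "II":
        return fit_method_ii(data, config.universal_Ps)
    return fit_method_iii(data)


def fit_batch_two_step(
    datasets: Sequence[CalibrationDataset],
    max_iter: int = 200,
    tolerance: float = 1e-10,
) -> tuple[float, list[FitResult]]:
    """Two-step batch fit yielding the batch-optimal saturation value.

    Step 1 fits every dataset freely (background-subtracted, P0 fixed to
    each film's background).  The batch-optimal Ps is the arithmetic mean
    of the fitted Ps values over all films *except* any flagged as the
    8-field reference, whose Ps is systematically depressed by
    inter-subfield scatter cross-talk.  Step 2 refits each film's slope
    with Ps pinned to the optimal value.

    Returns ``(optimal_Ps, results)`` with one step-2 result per input
    dataset, in order.
    """
    if len(datasets) < 2:
        raise ConfigError("batch fit needs at least 2 datasets")
    step1 = [fit_full(d, max_iter=max_iter, tolerance=tolerance) for d in datasets]
    ps_values = [
        r.params.Ps
        for r, d in zip(step1, datasets)
        if not d.is_eightfield_reference
    ]
    if len(ps_values) < 2:
        raise ConfigError("batch fit needs >= 2 non-reference datasets")
    optimal_Ps = float(np.mean(ps_values))

    results = []
    for d in datasets:
        P0 = d.background_pixel
        if P0 is None:
            raise ConfigError("batch refit requires a background per dataset")
        params = CalibrationParams(P0, optimal_Ps, _fit_m_only(P0, optimal_Ps, d))
        results.append(FitResult(params, "batch", _rms(params, d), len(d)))
    return optimal_Ps, results
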