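"""Calibration transfer between irradiation geometries via parameter ratios.

The sensitivity slope factorises as m = mE(E, FS, d) * mFP(FP): an
energy/geometry part and a film-processing part.  Taking the ratio of the
slope in some geometry to the slope of a reference curve measured *the
same day* cancels the processing factor, so the ratio depends only on
field size and depth and can be reused across days.  Similarly, the
saturation value of the multi-subfield (8-field) reference film sits in a
fixed ratio to the uniform-field ("standard") saturation value of the same
batch — the 8-field Ps is systematically low because of scatter cross-talk
between subfields and scanner non-uniformity.

A :class:`RatioModel` stores the Ps ratio and a table of m ratios keyed by
(field size, depth); :func:`derive_curve` applies it to turn one measured
reference curve into the curve for any tabulated geometry.

:func:`local_dose_error` quantifies the agreement of two curves as the
relative dose difference at equal pixel value — the figure of merit for
all curve comparisons in this package.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, FilmCalError
from .model import (
    CalibrationParams,
    IrradiationGeometry,
    dose_from_pixel,
    pixel_from_dose,
)

__all__ = [
    "RatioModel",
    "RatioLookupError",
    "compute_ps_ratio",
    "compute_m_ratio",
    "derive_curve",
    "local_dose_error",
    "LocalDoseErrorResult",
    "default_dose_grid",
]


class RatioLookupError(FilmCalError, KeyError):
    """Requested (field size, depth) absent from the m-ratio table."""


@dataclass(frozen=True)
class RatioModel:
    """Ps ratio and m-ratio lookup relative to an 8-field reference curve.

    ``ps_ratio`` is (mean standard-method Ps) / (8-field Ps).
    ``m_ratio_table`` maps (field_size cm, depth cm) -> m_standard/m_8field.
    Ratios are dimensionless and must be positive.  No interpolation is
    performed unless explicitly requested in :func:`derive_curve`.
    """

    ps_ratio: float
    m_ratio_table: dict[tuple[float, float], float] = field(default_factory=dict)
    reference_geometry: IrradiationGeometry | None = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ps_ratio) and self.ps_ratio > 0):
            raise DomainError(f"ps_ratio must be > 0, got {self.ps_ratio}")
        for key, ratio in self.m_ratio_table.items():
            if not (math.isfinite(ratio) and ratio > 0):
                raise DomainError(f"m ratio for {key} must be > 0, got {ratio}")

    def m_ratio(self, field_size: float, depth: float) -> float:
        try:
            return self.m_ratio_table[(field_size, depth)]
        except KeyError:
            raise RatioLookupError(
                f"no m ratio tabulated for field {field_size} cm, depth {depth} cm"
            ) from None

    def validate_physical_range(
        self, lo: float = 0.99, hi: float = 1.05
    ) -> list[str]:
        """Flag tabulated m ratios outside the physically expected band.

        For 6 MV beams on this film/scanner system the ratio lies in about
        [0.99, 1.05], decreasing with depth in the superficial build-up
        region (< 0.5 cm) and increasing with depth beyond it.  Returns a
        list of human-readable warnings (empty when all entries conform).
        """
        issues = []
        for (fs, d), r in sorted(self.m_ratio_table.items()):
            if not (lo <= r <= hi):
                issues.append(
                    f"m ratio {r:.3f} at field {fs} cm, depth {d} cm outside "
                    f"[{lo}, {hi}]"
                )
        return issues


def compute_ps_ratio(
    standard_params: list[CalibrationParams] | CalibrationParams,
    eightfield_params: CalibrationParams,
) -> float:
    """Ratio of (mean) standard-method Ps to the 8-field Ps."""
    if isinstance(standard_params, CalibrationParams):
        standard_params = [standard_params]
    if not standard_params:
        raise DomainError("need at least one standard parameter set")
    return float(np.mean([p.Ps for p in standard_params])) / eightfield_params.Ps


def compute_m_ratio(
    standard_params: CalibrationParams, eightfield_params: CalibrationParams
) -> float:
    """Slope ratio m_standard / m_8field.

    Only meaningful when both fits come from films processed the same day,
    so the film-processing factor cancels; the caller asserts the pairing.
    """
    return standard_params.m / eightfield_params.m


def derive_curve(
    reference: CalibrationParams,
    ratios: RatioModel,
    target: IrradiationGeometry,
    interpolate_depth: bool = False,
) -> CalibrationParams:
    """Derive the calibration curve for ``target`` from a reference curve.

    P0 is unchanged; Ps is scaled by the Ps ratio; m by the tabulated
    m ratio at the target (field size, depth).  With
    ``interpolate_depth=True`` a missing depth is linearly interpolated
    between tabulated depths at the same field size (never extrapolated).
    """
    try:
        mr = ratios.m_ratio(target.field_size, target.depth)
    except RatioLookupError:
        if not interpolate_depth:
            raise
        depths = sorted(
            d for (fs, d) in ratios.m_ratio_table if fs == target.field_size
        )
        below = [d for d in depths if d < target.depth]
        above = [d for d in depths if d > target.depth]
        if not below or not above:
            raise RatioLookupError(
                f"depth {target.depth} cm not bracketed by table entries for "
                f"field {target.field_size} cm"
            ) from None
        d0, d1 = below[-1], above[0]
        r0 = ratios.m_ratio_table[(target.field_size, d0)]
        r1 = ratios.m_ratio_table[(target.field_size, d1)]
        mr = r0 + (r1 - r0) * (target.depth - d0) / (d1 - d0)
    return CalibrationParams(
        reference.P0, reference.Ps * ratios.ps_ratio, reference.m * mr
    )


def default_dose_grid(lo: float = 10.0, hi: float = 150.0, step: float = 1.0):
    """1-cGy grid over the clinically useful range [10, 150] cGy.

    Below 10 cGy the comparison is background-dominated: relative errors
    blow up while the absolute dose difference stays within ~0.1 cGy, so
    that region is reported separately when needed.
    """
    n = int(round((hi - lo) / step))
    return np.linspace(lo, hi, n + 1)


@dataclass(frozen=True)
class LocalDoseErrorResult:
    """Per-dose relative errors of a test curve against a truth curve."""

    doses: np.ndarray
    errors: np.ndarray          # (D_test - D_true)/D_true; NaN where flagged
    max_abs_error: float        # over non-flagged grid points
    flagged: np.ndarray         # True where the truth pixel was not invertible

    @property
    def max_abs_error_percent(self) -> float:
        return 100.0 * self.max_abs_error


def local_dose_error(
    test: CalibrationParams,
    truth: CalibrationParams,
    dose_grid=None,
) -> LocalDoseErrorResult:
    """Local relative dose error of ``test`` against ``truth``.

    For each grid dose D the truth curve gives a pixel value P; inverting
    P through the *test* curve gives the dose that would be reported if
    the test curve were used.  The local dose error is
    (D_test - D) / D — the dose difference relative to the true dose at
    the same pixel value.

    Grid points whose truth pixel falls outside the test curve's
    invertible range are flagged (NaN error, excluded from the maximum)
    with a warning rather than aborting the whole comparison.
    """
    grid = default_dose_grid() if dose_grid is None else np.asarray(dose_grid, float)
    if np.any(grid <= 0):
        raise DomainError("dose grid must be strictly positive")
    truth_pixels = pixel_from_dose(truth, grid)

    errors = np.full(grid.shape, np.nan)
    flagged = np.zeros(grid.shape, dtype=bool)
    # invertible range of the test curve: [P0, P0 + Ps)
    ok = (truth_pixels >= test.P0) & (
        truth_pixels < test.P0 + test.Ps * (1 - 1e-9)
    )
    flagged[~ok] = True
    if np.any(ok):
        d_test = dose_from_pixel(test, truth_pixels[ok])
        errors[ok] = (d_test - grid[ok]) / grid[ok]
    if np.any(flagged):
        warnings.warn(
            f"{int(flagged.sum())} grid dose(s) outside the test curve's "
            "invertible range were excluded",
            stacklevel=2,
        )
    if not np.any(ok):
        raise DomainError("no grid dose is invertible through the test curve")
    max_abs = float(np.nanmax(np.abs(errors)))
    return LocalDoseErrorResult(grid, errors, max_abs, flagged)
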