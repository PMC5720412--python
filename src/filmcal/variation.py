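"""Ensemble statistics of fitted calibration parameters.

Films processed on different days (and drawn from different emulsion
batches) yield different fitted (P0, Ps, m).  Intra-day ensembles isolate
batch-to-batch variation of the saturation value; inter-day ensembles add
the day-to-day film-processing variation that dominates the slope.  This
module summarises such ensembles (mean and relative sample SD per
parameter) and reports the worst-case disagreement between ensemble
members as a local dose spread.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .errors import DomainError
from .model import CalibrationParams
from .transfer import local_dose_error

__all__ = ["ParameterEnsemble", "EnsembleStatistics", "ensemble_statistics",
           "ensemble_dose_spread"]


@dataclass(frozen=True)
class ParameterEnsemble:
    """Fitted parameter sets labelled by acquisition day and film batch."""

    entries: tuple[tuple[CalibrationParams, str, str], ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))

    @property
    def params(self) -> list[CalibrationParams]:
        return [e[0] for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class EnsembleStatistics:
    """Per-parameter mean and relative sample SD (1-sigma, percent)."""

    mean: dict[str, float]
    rel_sd_percent: dict[str, float]
    n: int


def ensemble_statistics(ens: ParameterEnsemble) -> EnsembleStatistics:
    """Mean and relative sample SD of P0, Ps, m over the ensemble.

    The SD uses the n-1 denominator (these are small samples, typically
    7-12 films); the relative SD is SD/mean in percent.
    """
    if len(ens) < 2:
        raise DomainError("ensemble statistics need >= 2 entries")
    arr = np.array([[p.P0, p.Ps, p.m] for p in ens.params])
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    names = ("P0", "Ps", "m")
    return EnsembleStatistics(
        mean=dict(zip(names, mean.tolist())),
        rel_sd_percent=dict(zip(names, (100.0 * sd / mean).tolist())),
        n=len(ens),
    )


def ensemble_dose_spread(ens: ParameterEnsemble, dose_grid) -> float:
    """Maximum pairwise local dose disagreement over the grid (fraction).

    Every unordered pair of curves is compared in both directions (either
    member may serve as the truth curve; there is no privileged
    reference), and the maximum absolute local dose error over all pairs,
    directions and grid doses is returned.  Pairs with inversion-range
    violations at some grid doses contribute only their invertible points.
    """
    if len(ens) < 2:
        raise DomainError("dose spread needs >= 2 entries")
    worst = 0.0
    for a, b in combinations(ens.params, 2):
        for test, truth in ((a, b), (b, a)):
            res = local_dose_error(test, truth, dose_grid)
            worst = max(worst, res.max_abs_error)
    return worst
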