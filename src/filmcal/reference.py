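"""Bundled reference calibration data for a 6 MV beam / XV-film system.

A published reference study of this film/scanner class reports fitted
response-curve parameters for three irradiation geometries, each measured
with a background film plus eight dose points (16-128 cGy) and refitted
under the reduced-point strategies (Methods I-III).  Those parameter sets
are bundled here: they power the examples, serve as ground truth for the
curve-comparison validation, and illustrate the regime where a universal
saturation value breaks down (geometry 3's batch has a Ps about 9% below
the universal value).

Universal values: background 245 counts; saturation 3542 counts, obtained
from the 8-field reference mean Ps of 3271 scaled by the standard-to-
8-field Ps ratio of 1.083.

Inter-day parameter variability of the same system (12 films over three
years): means (245, 3271, 31.7) with relative SDs (1.8%, 5.7%, 7.7%);
intra-day (same-day) variability: Ps 1.8%, m 0.8% around means
(3310, 33.9).
"""

from __future__ import annotations

from .model import CalibrationParams, IrradiationGeometry

__all__ = [
    "UNIVERSAL_P0",
    "UNIVERSAL_PS",
    "EIGHTFIELD_MEAN_PS",
    "PS_RATIO_STANDARD_TO_EIGHTFIELD",
    "INTERDAY_MEAN_PARAMS",
    "INTERDAY_REL_SD",
    "INTRADAY_REL_SD",
    "GEOMETRIES",
    "FULL_FIT",
    "METHOD_FITS",
]

#: Universal background pixel value (counts).
UNIVERSAL_P0 = 245.0

#: Universal saturation pixel value (counts): 3271 x 1.083, rounded.
UNIVERSAL_PS = 3542.0

#: Mean 8-field-method saturation value over the inter-day ensemble.
EIGHTFIELD_MEAN_PS = 3271.0

#: Standard-method to 8-field-method saturation ratio (0.5% 1-sigma).
PS_RATIO_STANDARD_TO_EIGHTFIELD = 1.083

#: Inter-day ensemble mean parameters (12 films, three years).
INTERDAY_MEAN_PARAMS = CalibrationParams(245.0, 3271.0, 31.7)

#: Inter-day relative SDs of (P0, Ps, m), 1-sigma fractions.
INTERDAY_REL_SD = (0.018, 0.057, 0.077)

#: Intra-day relative SDs of (Ps, m), 1-sigma fractions.
INTRADAY_REL_SD = (0.018, 0.008)

#: The three reference irradiation geometries (SSD cm, square field cm,
#: depth cm).  Geometry 2 is the 8-field reference geometry itself.
GEOMETRIES: dict[int, IrradiationGeometry] = {
    1: IrradiationGeometry(ssd=90.0, field_size=20.0, depth=10.0),
    2: IrradiationGeometry(ssd=95.0, field_size=10.0, depth=5.0),
    3: IrradiationGeometry(ssd=90.0, field_size=5.0, depth=10.0),
}

#: Eight-point fits (one background film + eight dose points) per geometry.
FULL_FIT: dict[int, CalibrationParams] = {
    1: CalibrationParams(247.0, 3585.0, 30.80),
    2: CalibrationParams(240.0, 3577.0, 33.58),
    3: CalibrationParams(254.0, 3209.0, 40.18),
}

#: Reduced-point fits per geometry.  Keys: Ia/Ib = universal P0 and Ps with
#: one/two dose points; IIa/IIb = universal Ps, measured background,
#: one/two points; IIIa/IIIb = measured background, two/three points.
METHOD_FITS: dict[int, dict[str, CalibrationParams]] = {
    1: {
        "Ia": CalibrationParams(245.0, 3542.0, 31.28),
        "Ib": CalibrationParams(245.0, 3542.0, 31.17),
        "IIa": CalibrationParams(247.0, 3542.0, 31.23),
        "IIb": CalibrationParams(247.0, 3542.0, 31.11),
        "IIIa": CalibrationParams(247.0, 3558.0, 30.91),
        "IIIb": CalibrationParams(247.0, 3538.0, 31.10),
    },
    2: {
        "Ia": CalibrationParams(245.0, 3542.0, 33.37),
        "Ib": CalibrationParams(245.0, 3542.0, 33.48),
        "IIa": CalibrationParams(240.0, 3542.0, 33.50),
        "IIb": CalibrationParams(240.0, 3542.0, 33.63),
        "IIIa": CalibrationParams(240.0, 3494.0, 33.95),
        "IIIb": CalibrationParams(240.0, 3506.0, 33.80),
    },
    3: {
        "Ia": CalibrationParams(245.0, 3542.0, 37.62),
        "Ib": CalibrationParams(245.0, 3542.0, 38.28),
        "IIa": CalibrationParams(254.0, 3542.0, 37.36),
        "IIb": CalibrationParams(254.0, 3542.0, 37.98),
        "IIIa": CalibrationParams(254.0, 3200.0, 40.19),
        "IIIb": CalibrationParams(254.0, 3200.0, 40.16),
    },
}
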