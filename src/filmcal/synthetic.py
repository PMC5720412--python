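"""Synthetic data emulating the film-calibration measurement chain.

Three layers of emulation, each reproducible from a seed:

* **parameter draws** — day-to-day (or film-to-film) variation of the
  response-curve parameters as independent Gaussian relative
  perturbations around a mean curve.  Defaults reproduce the observed
  inter-day variability of an XV-film / automatic-processor system over
  several years: 1.8% on P0, 5.7% on Ps and 7.7% on m (1-sigma), with the
  much tighter same-day values 1.8% (Ps) and 0.8% (m) available for
  intra-day ensembles.
* **calibration datasets** — (dose, pixel) points with ~1% Gaussian
  relative readout noise, plus a noisy background-film reading.
* **film images** — a 2-D pixel map of one 8-field calibration film:
  eight 3x3 cm^2 subfields at doses spanning 16-128 cGy on a uniform
  background, at the 0.123 mm scanner pitch, with optional inter-subfield
  scatter cross-talk.  ROI extraction averages pixels at a subfield
  centre exactly as scanned films are read out.

What is *not* emulated: radiation transport, film-grain statistics,
processor chemistry drift within a day, scanner PSF/glare, and any
correlation between parameters (none is known).  Noise is Gaussian and
relative — scanner counts here are post-processed ROI averages, far from
Poisson-limited.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DomainError
from .fitting import CalibrationDataset
from .model import CalibrationParams, DosePoint, IrradiationGeometry, pixel_from_dose

__all__ = [
    "GeneratorConfig",
    "FilmImage",
    "DEFAULT_DOSE_SCHEDULE",
    "draw_day_params",
    "generate_dataset",
    "default_eightfield_layout",
    "render_eightfield_image",
    "extract_roi",
    "write_film_image",
    "read_film_image",
]

#: Eight subfield doses (cGy) spanning the 16-128 cGy calibration range.
DEFAULT_DOSE_SCHEDULE: tuple[float, ...] = (16, 24, 32, 48, 64, 80, 96, 128)

#: Scanner readout pitch, mm per pixel.
DEFAULT_PITCH_MM = 0.123


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for synthetic-data generation.

    Relative SDs are 1-sigma fractions; ``inter_day_rel_sd`` applies to
    (P0, Ps, m), ``intra_day_rel_sd`` to (Ps, m) with P0 treated as stable
    within a day.
    """

    mean_params: CalibrationParams = CalibrationParams(245.0, 3271.0, 31.7)
    inter_day_rel_sd: tuple[float, float, float] = (0.018, 0.057, 0.077)
    intra_day_rel_sd: tuple[float, float] = (0.018, 0.008)
    readout_rel_noise: float = 0.01
    dose_schedule: tuple[float, ...] = DEFAULT_DOSE_SCHEDULE
    seed: int | None = None

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.inter_day_rel_sd + self.intra_day_rel_sd):
            raise ConfigError("relative SDs must be >= 0")
        if self.readout_rel_noise < 0:
            raise ConfigError("readout_rel_noise must be >= 0")
        if not self.dose_schedule:
            raise ConfigError("dose_schedule must be non-empty")
        if any(not (0 < d <= 200) for d in self.dose_schedule):
            raise ConfigError("doses must lie in (0, 200] cGy")
        object.__setattr__(self, "dose_schedule", tuple(self.dose_schedule))


@dataclass(frozen=True)
class FilmImage:
    """Scanned-film pixel map with physical pitch and subfield layout.

    Row-major array, origin at top-left; the physical position of pixel
    (i, j) is (i*pitch, j*pitch) mm with half-open pixel footprints.
    ``subfield_layout`` records the centre (row_mm, col_mm) and dose of
    each subfield.
    """

    pixels: np.ndarray
    pitch: float = DEFAULT_PITCH_MM
    subfield_layout: tuple[tuple[float, float, float], ...] = field(
        default_factory=tuple
    )

    def __post_init__(self) -> None:
        if self.pitch <= 0:
            raise DomainError("pitch must be > 0")
        h, w = self.pixels.shape
        for r, c, _ in self.subfield_layout:
            if not (0 <= r <= h * self.pitch and 0 <= c <= w * self.pitch):
                raise DomainError("subfield layout outside image bounds")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def draw_day_params(
    config: GeneratorConfig,
    n_days: int,
    seed: int | None = None,
    which: str = "inter",
) -> list[CalibrationParams]:
    """Draw per-day response-curve parameters.

    Independent Gaussian relative perturbations of the mean parameters;
    ``which="inter"`` perturbs all three parameters at the inter-day SDs,
    ``which="intra"`` only (Ps, m) at the intra-day SDs.  Draws violating
    parameter positivity are redrawn (the count is reported via a
    warning); if more than 10% of draws are rejected the configuration is
    refused as unphysical.
    """
    if n_days < 1:
        raise DomainError("n_days must be >= 1")
    if which == "inter":
        sd = config.inter_day_rel_sd
    elif which == "intra":
        sd = (0.0,) + config.intra_day_rel_sd
    else:
        raise ConfigError(f"which must be 'inter' or 'intra', got {which!r}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    mean = config.mean_params
    out: list[CalibrationParams] = []
    n_rejected = 0
    while len(out) < n_days:
        k = rng.normal(1.0, sd, size=3)
        if np.any(k <= 0):
            n_rejected += 1
            if n_rejected > 0.1 * (n_days + n_rejected):
                raise ConfigError(
                    "relative SDs so large that >10% of draws violate "
                    "parameter positivity"
                )
            continue
        out.append(
            CalibrationParams(mean.P0 * k[0], mean.Ps * k[1], mean.m * k[2])
        )
    if n_rejected:
        warnings.warn(f"redrew {n_rejected} parameter draw(s)", stacklevel=2)
    return out


def generate_dataset(
    params: CalibrationParams,
    dose_schedule=DEFAULT_DOSE_SCHEDULE,
    readout_rel_noise: float = 0.01,
    seed: int | None = None,
    geometry: IrradiationGeometry | None = None,
    batch_id: str = "",
    day_id: str = "",
    is_eightfield_reference: bool = False,
) -> CalibrationDataset:
    """Simulate one calibration film set: noisy pixels at each dose plus a
    noisy background-film reading.

    Pixel = model value times (1 + eps) with eps ~ N(0, readout noise);
    the background reading gets an independent eps.  If the noise happens
    to break pixel monotonicity the set is regenerated (up to 5 attempts,
    with a warning) since a non-monotone calibration set would be rejected
    at fit time.
    """
    if not len(dose_schedule):
        raise DomainError("dose_schedule must be non-empty")
    rng = np.random.default_rng(seed)
    doses = np.asarray(sorted(dose_schedule), float)
    clean = pixel_from_dose(params, doses)
    for attempt in range(5):
        noisy = clean * (1 + rng.normal(0, readout_rel_noise, size=doses.size))
        background = params.P0 * (1 + rng.normal(0, readout_rel_noise))
        if np.all(np.diff(noisy) > 0):
            if attempt:
                warnings.warn(
                    f"regenerated noisy pixels {attempt} time(s) to restore "
                    "monotonicity",
                    stacklevel=2,
                )
            return CalibrationDataset(
                points=tuple(
                    DosePoint(float(d), float(p)) for d, p in zip(doses, noisy)
                ),
                background_pixel=float(background),
                geometry=geometry,
                batch_id=batch_id,
                day_id=day_id,
                is_eightfield_reference=is_eightfield_reference,
            )
    raise DomainError(
        "could not generate a monotone pixel sequence in 5 attempts: "
        "noise too large for the dose spacing"
    )


def default_eightfield_layout(
    dose_schedule=DEFAULT_DOSE_SCHEDULE,
    subfield_cm: float = 3.0,
    gap_cm: float = 1.0,
) -> list[tuple[float, float, float]]:
    """Subfield centres (row_mm, col_mm, dose) for a 2x4 subfield grid.

    3x3 cm^2 subfields separated and bordered by 1 cm of unexposed film.
    """
    if len(dose_schedule) != 8:
        raise ConfigError("the 8-field layout needs exactly 8 doses")
    sub, gap = 10.0 * subfield_cm, 10.0 * gap_cm
    layout = []
    for k, dose in enumerate(dose_schedule):
        row, col = divmod(k, 4)
        r = gap + sub / 2 + row * (sub + gap)
        c = gap + sub / 2 + col * (sub + gap)
        layout.append((r, c, float(dose)))
    return layout


def render_eightfield_image(
    params: CalibrationParams,
    layout=None,
    noise: float = 0.01,
    seed: int | None = None,
    pitch: float = DEFAULT_PITCH_MM,
    subfield_cm: float = 3.0,
    gap_cm: float = 1.0,
    crosstalk: float = 0.0,
) -> FilmImage:
    """Render a synthetic scanned 8-field calibration film.

    Each 3x3 cm^2 subfield is filled with the model pixel value for its
    dose; everywhere else is background P0.  Per-pixel Gaussian relative
    noise emulates readout.  ``crosstalk`` adds the given fraction of each
    *adjacent* subfield's dose to a subfield's own dose before evaluating
    the model — a crude stand-in for inter-field scatter, which depresses
    the apparent saturation value fitted from 8-field films.
    """
    if layout is None:
        layout = default_eightfield_layout(subfield_cm=subfield_cm, gap_cm=gap_cm)
    sub_px = int(10.0 * subfield_cm / pitch)  # pixels per subfield edge
    half = sub_px // 2

    # bounding canvas from the layout extents
    max_r = max(r for r, _, _ in layout) + 10.0 * (subfield_cm / 2 + gap_cm)
    max_c = max(c for _, c, _ in layout) + 10.0 * (subfield_cm / 2 + gap_cm)
    h, w = int(round(max_r / pitch)), int(round(max_c / pitch))

    doses = [d for _, _, d in layout]
    effective = list(doses)
    if crosstalk:
        centres = [(r, c) for r, c, _ in layout]
        for i, (ri, ci) in enumerate(centres):
            for j, (rj, cj) in enumerate(centres):
                if i == j:
                    continue
                # adjacent = centre-to-centre distance of one grid step
                if math.hypot(ri - rj, ci - cj) <= 10.0 * (subfield_cm + gap_cm) * 1.01:
                    effective[i] += crosstalk * doses[j]

    img = np.full((h, w), params.P0, dtype=float)
    occupied = np.zeros((h, w), dtype=bool)
    for (r, c, _), dose_eff in zip(layout, effective):
        i0 = int(round(r / pitch)) - half
        j0 = int(round(c / pitch)) - half
        if i0 < 0 or j0 < 0 or i0 + sub_px > h or j0 + sub_px > w:
            raise DomainError("subfield extends outside the image")
        block = (slice(i0, i0 + sub_px), slice(j0, j0 + sub_px))
        if occupied[block].any():
            raise DomainError("subfields overlap")
        occupied[block] = True
        img[block] = pixel_from_dose(params, dose_eff)
    if noise:
        rng = np.random.default_rng(seed)
        img = img * (1 + rng.normal(0, noise, size=img.shape))
    return FilmImage(pixels=img, pitch=pitch, subfield_layout=tuple(layout))


def extract_roi(image: FilmImage, center_mm: tuple[float, float], size_mm: float) -> float:
    """Mean pixel value over a square ROI centred at ``center_mm``.

    The ROI is the half-open square [c - s/2, c + s/2) in each axis;
    a pixel contributes iff its centre (index + 0.5)*pitch lies inside.
    At the default 0.123 mm pitch a 1.23 mm ROI covers exactly 10x10
    pixels and a 12.3 mm ROI 100x100.
    """
    if size_mm <= 0:
        raise DomainError("ROI size must be > 0")
    h, w = image.shape
    r, c = center_mm
    lo_r, hi_r = r - size_mm / 2, r + size_mm / 2
    lo_c, hi_c = c - size_mm / 2, c + size_mm / 2
    if lo_r < 0 or lo_c < 0 or hi_r > h * image.pitch or hi_c > w * image.pitch:
        raise DomainError("ROI extends outside the image")
    i0 = int(np.ceil(lo_r / image.pitch - 0.5))
    i1 = int(np.ceil(hi_r / image.pitch - 0.5))
    j0 = int(np.ceil(lo_c / image.pitch - 0.5))
    j1 = int(np.ceil(hi_c / image.pitch - 0.5))
    if i1 <= i0 or j1 <= j0:
        raise DomainError("ROI smaller than one pixel")
    return float(image.pixels[i0:i1, j0:j1].mean())


def write_film_image(image: FilmImage, path) -> None:
    """Write the image as single-channel 16-bit TIFF; the pitch (mm) is
    recorded in the ImageDescription tag as JSON."""
    import json

    import tifffile

    data = np.clip(np.round(image.pixels), 0, 65535).astype(np.uint16)
    tifffile.imwrite(
        path,
        data,
        description=json.dumps(
            {"pitch_mm": image.pitch, "subfield_layout": list(image.subfield_layout)}
        ),
    )


def read_film_image(path) -> FilmImage:
    """Read a TIFF written by :func:`write_film_image`."""
    import json

    import tifffile

    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        data = page.asarray().astype(float)
        meta = {}
        desc = page.tags.get("ImageDescription")
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (ValueError, TypeError):
                meta = {}
    return FilmImage(
        pixels=data,
        pitch=float(meta.get("pitch_mm", DEFAULT_PITCH_MM)),
        subfield_layout=tuple(tuple(t) for t in meta.get("subfield_layout", ())),
    )
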