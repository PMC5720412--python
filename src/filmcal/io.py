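"""Readers and writers for the filmcal interchange formats.

JSON is the canonical parameter/ratio/budget interchange (parameters carry
nested metadata); CSV is used only for flat point tables and parameter
ensembles.  All doses are cGy throughout — there is no unit-conversion
layer.

Formats
-------
points CSV          ``dose_cGy,pixel`` (one row per point)
dataset JSON        ``{"points": [{"dose_cGy":..., "pixel":...}, ...],
                    "background_pixel":..., "geometry": {"ssd_cm":...,
                    "field_cm":..., "depth_cm":...}, "batch_id":...,
                    "day_id":...}``
params JSON         ``{"P0":..., "Ps":..., "m":..., "method":..., "rms":...}``
ratio-model JSON    ``{"ps_ratio":..., "reference": {...}, "table":
                    [{"field_cm":..., "depth_cm":..., "m_ratio":...}, ...]}``
budget JSON         ``{"rel_sigma_Ps":..., "rel_sigma_m":...,
                    "rel_sigma_P":..., "rel_sigma_P0":...}``
ensemble CSV        ``day_id,batch_id,P0,Ps,m`` (one row per film)
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .errors import ConfigError
from .fitting import CalibrationDataset, FitResult
from .model import CalibrationParams, DosePoint, IrradiationGeometry
from .synthetic import GeneratorConfig
from .transfer import RatioModel
from .uncertainty import UncertaintyBudget
from .variation import ParameterEnsemble

__all__ = [
    "read_points_csv",
    "write_points_csv",
    "read_dataset_json",
    "write_dataset_json",
    "read_params_json",
    "write_params_json",
    "read_ratio_model_json",
    "write_ratio_model_json",
    "read_budget_json",
    "read_ensemble_csv",
    "write_ensemble_csv",
    "read_generator_config",
]


def read_points_csv(path) -> list[DosePoint]:
    """Read a ``dose_cGy,pixel`` table."""
    df = pd.read_csv(path)
    missing = {"dose_cGy", "pixel"} - set(df.columns)
    if missing:
        raise ConfigError(f"{path}: missing column(s) {sorted(missing)}")
    return [DosePoint(float(r.dose_cGy), float(r.pixel)) for r in df.itertuples()]


def write_points_csv(points, path) -> None:
    pd.DataFrame(
        {"dose_cGy": [p.dose for p in points], "pixel": [p.pixel for p in points]}
    ).to_csv(path, index=False)


def _geometry_from_dict(d: dict | None) -> IrradiationGeometry | None:
    if d is None:
        return None
    return IrradiationGeometry(
        ssd=float(d["ssd_cm"]),
        field_size=float(d["field_cm"]),
        depth=float(d["depth_cm"]),
        energy=str(d.get("energy", "6MV")),
    )


def _geometry_to_dict(g: IrradiationGeometry | None) -> dict | None:
    if g is None:
        return None
    return {
        "ssd_cm": g.ssd,
        "field_cm": g.field_size,
        "depth_cm": g.depth,
        "energy": g.energy,
    }


def read_dataset_json(path) -> CalibrationDataset:
    raw = json.loads(Path(path).read_text())
    try:
        points = tuple(
            DosePoint(float(p["dose_cGy"]), float(p["pixel"]))
            for p in raw["points"]
        )
    except KeyError as exc:
        raise ConfigError(f"{path}: point missing field {exc}") from None
    bg = raw.get("background_pixel")
    return CalibrationDataset(
        points=points,
        background_pixel=None if bg is None else float(bg),
        geometry=_geometry_from_dict(raw.get("geometry")),
        batch_id=str(raw.get("batch_id", "")),
        day_id=str(raw.get("day_id", "")),
        is_eightfield_reference=bool(raw.get("is_eightfield_reference", False)),
    )


def write_dataset_json(dataset: CalibrationDataset, path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "points": [
                    {"dose_cGy": p.dose, "pixel": p.pixel} for p in dataset.points
                ],
                "background_pixel": dataset.background_pixel,
                "geometry": _geometry_to_dict(dataset.geometry),
                "batch_id": dataset.batch_id,
                "day_id": dataset.day_id,
                "is_eightfield_reference": dataset.is_eightfield_reference,
            },
            indent=2,
        )
    )


def read_params_json(path) -> CalibrationParams:
    raw = json.loads(Path(path).read_text())
    try:
        return CalibrationParams(float(raw["P0"]), float(raw["Ps"]), float(raw["m"]))
    except KeyError as exc:
        raise ConfigError(f"{path}: missing parameter {exc}") from None


def write_params_json(result: FitResult | CalibrationParams, path, **extra) -> None:
    if isinstance(result, FitResult):
        payload = result.as_dict()
    else:
        payload = result.as_dict()
    payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2))


def read_ratio_model_json(path) -> RatioModel:
    raw = json.loads(Path(path).read_text())
    table = {
        (float(e["field_cm"]), float(e["depth_cm"])): float(e["m_ratio"])
        for e in raw.get("table", [])
    }
    return RatioModel(
        ps_ratio=float(raw["ps_ratio"]),
        m_ratio_table=table,
        reference_geometry=_geometry_from_dict(raw.get("reference")),
    )


def write_ratio_model_json(model: RatioModel, path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "ps_ratio": model.ps_ratio,
                "reference": _geometry_to_dict(model.reference_geometry),
                "table": [
                    {"field_cm": fs, "depth_cm": d, "m_ratio": r}
                    for (fs, d), r in sorted(model.m_ratio_table.items())
                ],
            },
            indent=2,
        )
    )


def read_budget_json(path) -> UncertaintyBudget:
    raw = json.loads(Path(path).read_text())
    return UncertaintyBudget(
        rel_sigma_Ps=float(raw.get("rel_sigma_Ps", 0.005)),
        rel_sigma_m=float(raw.get("rel_sigma_m", 0.01)),
        rel_sigma_P=float(raw.get("rel_sigma_P", 0.01)),
        rel_sigma_P0=float(raw.get("rel_sigma_P0", 0.005)),
    )


def read_ensemble_csv(path) -> ParameterEnsemble:
    """Read ``day_id,batch_id,P0,Ps,m`` rows into an ensemble."""
    df = pd.read_csv(path)
    missing = {"day_id", "batch_id", "P0", "Ps", "m"} - set(df.columns)
    if missing:
        raise ConfigError(f"{path}: missing column(s) {sorted(missing)}")
    entries = tuple(
        (
            CalibrationParams(float(r.P0), float(r.Ps), float(r.m)),
            str(r.day_id),
            str(r.batch_id),
        )
        for r in df.itertuples()
    )
    return ParameterEnsemble(entries=entries)


def write_ensemble_csv(ens: ParameterEnsemble, path) -> None:
    pd.DataFrame(
        [
            {"day_id": day, "batch_id": batch, "P0": p.P0, "Ps": p.Ps, "m": p.m}
            for p, day, batch in ens.entries
        ]
    ).to_csv(path, index=False)


def read_generator_config(path) -> GeneratorConfig:
    """Read a generator config from JSON or YAML (by extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    mean = raw.get("mean_params")
    kwargs = {}
    if mean is not None:
        kwargs["mean_params"] = CalibrationParams(
            float(mean["P0"]), float(mean["Ps"]), float(mean["m"])
        )
    for key in ("inter_day_rel_sd", "intra_day_rel_sd", "dose_schedule"):
        if key in raw:
            kwargs[key] = tuple(float(v) for v in raw[key])
    for key in ("readout_rel_noise", "seed"):
        if key in raw and raw[key] is not None:
            kwargs[key] = raw[key]
    return GeneratorConfig(**kwargs)
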