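"""File I/O: plate photographs, calibration models, run configs, results."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, FormatError
from .pipeline import CropRect, PipelineConfig, PlateImage
from .quantitation import CalibrationModel, QuantConfig, SampleResult

__all__ = [
    "read_plate", "write_plate_png", "save_model", "load_model",
    "load_run_config", "save_results", "results_frame", "config_hash",
]


def read_plate(path, *, origin_row: int | None = None,
               front_row: int | None = None,
               crop: tuple[int, int, int, int] | None = None) -> PlateImage:
    """Read an 8-bit RGB photograph (PNG/JPEG/TIFF) as a PlateImage.

    ``crop`` is (top, left, bottom, right), half-open; its top row is taken
    as the solvent front and its bottom boundary row as the origin line
    unless those are given explicitly.  Without a crop the full image height
    is used.
    """
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(f"{path}: expected an RGB image, got shape {arr.shape}")
    if crop is not None:
        top, left, bottom, right = crop
        rect = CropRect(top, left, bottom, right)
    else:
        rect = None
    fr = front_row if front_row is not None else (rect.top if rect else 0)
    orow = origin_row if origin_row is not None else (
        rect.bottom - 1 if rect else arr.shape[0] - 1)
    if rect is None:
        rect = CropRect(fr, 0, orow + 1, arr.shape[1])
    return PlateImage(pixels=arr.astype(np.uint8), origin_row=orow,
                      front_row=fr, crop=rect)


def write_plate_png(path, img: PlateImage | np.ndarray) -> None:
    arr = img.pixels if isinstance(img, PlateImage) else np.asarray(img)
    if arr.ndim == 2:
        arr = np.clip(np.rint(arr * 255.0), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), arr)


def save_model(model: CalibrationModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model.to_dict(), fh, sort_keys=True)


def load_model(path) -> CalibrationModel:
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"model file not found: {p}")
    with open(p) as fh:
        d = yaml.safe_load(fh)
    try:
        return CalibrationModel.from_dict(d)
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"malformed model file {p}: {exc}") from exc


def load_run_config(path) -> dict:
    """Merged run configuration: pipeline/quant settings and a standards
    registry mapping drug name -> {standard_rf, label_claim_mg, tolerance_frac}.
    """
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    with open(p) as fh:
        raw = yaml.safe_load(fh) or {}
    out = {
        "pipeline": PipelineConfig(**raw.get("pipeline", {})),
        "quant": QuantConfig(**raw.get("quant", {})),
        "standards": raw.get("standards", {}),
    }
    for drug, entry in out["standards"].items():
        if "standard_rf" not in entry:
            raise ConfigError(f"standards entry {drug!r} lacks standard_rf")
    return out


def config_hash(*cfgs) -> str:
    """Stable short hash of one or more config dataclasses/dicts."""
    blob = json.dumps([
        dataclasses.asdict(c) if dataclasses.is_dataclass(c) else c
        for c in cfgs
    ], sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def results_frame(results: list[SampleResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "sample_id": r.sample_id,
            "rf": None if r.rf is None else round(r.rf, 2),
            "rf_ok": r.rf_ok,
            "conc_mg_ml": None if r.conc_mg_ml is None else round(r.conc_mg_ml, 2),
            "api_mg_per_tablet": (None if r.api_mg_per_tablet is None
                                  else round(r.api_mg_per_tablet, 2)),
            "content_ok": r.content_ok,
            "verdict": r.verdict,
        })
    return pd.DataFrame(rows)


def save_results(results: list[SampleResult], prefix) -> tuple[Path, Path]:
    """Write results as <prefix>.csv and <prefix>.json; returns both paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    df = results_frame(results)
    csv_path = prefix.with_suffix(".csv")
    json_path = prefix.with_suffix(".json")
    df.to_csv(csv_path, index=False)
    with open(json_path, "w") as fh:
        json.dump(df.to_dict(orient="records"), fh, indent=2)
    return csv_path, json_path
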