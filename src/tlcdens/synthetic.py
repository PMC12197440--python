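"""Ground-truthed synthetic TLC plate renderer.

Emulates an F254 plate photographed under short-wave UV: a bright green
fluorescent background on which the analyte appears as dark *quench* spots.
Each spot is a subtractive 2-D Gaussian in the green channel; a linear
illumination gradient and Gaussian pixel noise emulate real capture
conditions, and the result is quantized to 8 bits before any analysis so
tests exercise the same precision regime as real photographs.

The manifest records, for every rendered spot, its true centroid, Rf and the
analytic area under the curve 2*pi*amplitude*sigma^2 — both in raw green
units and rescaled by the rendered image's min-max range, i.e. in the units
the detection pipeline's inverted-normalized signal reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, GeometryError
from .pipeline import PlateImage

__all__ = [
    "SpotSpec", "LaneSpec", "SyntheticPlateSpec", "GroundTruthManifest",
    "render_plate", "build_assay_spec", "render_calibration_set",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class SpotSpec:
    rf_true: float
    amplitude: float     # green-channel quench depth, in (0, 1]
    sigma_px: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.rf_true <= 1.0):
            raise GeometryError(f"rf_true must be in [0, 1], got {self.rf_true}")
        if not (0.0 < self.amplitude <= 1.0):
            raise ConfigError(f"amplitude must be in (0, 1], got {self.amplitude}")
        if self.sigma_px <= 0:
            raise ConfigError(f"sigma_px must be > 0, got {self.sigma_px}")


@dataclass(frozen=True)
class LaneSpec:
    column_center: float
    spots: tuple[SpotSpec, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "spots", tuple(self.spots))


@dataclass(frozen=True)
class SyntheticPlateSpec:
    """Layout and imaging conditions of one synthetic plate.

    Defaults model the study conditions: a 400-row development region (the
    pipeline's standard height), bright background at ~85% of full scale,
    mild pixel noise (sd 0.005 of full scale, i.e. ~1.3 of 255 counts) and no
    illumination gradient unless requested.
    """

    width: int = 360
    height: int = 400
    lanes: tuple[LaneSpec, ...] = ()
    background_green: float = 0.85
    gradient: tuple[float, float] = (0.0, 0.0)  # full-span slope per (row, col) axis
    noise_sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "lanes", tuple(self.lanes))
        if self.width < 32 or self.height < 32:
            raise ConfigError("plate must be at least 32 x 32 pixels")
        if not (0.0 < self.background_green <= 1.0):
            raise ConfigError("background_green must be in (0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        for lane in self.lanes:
            if not (0 <= lane.column_center <= self.width - 1):
                raise GeometryError(
                    f"lane center {lane.column_center} outside [0, {self.width - 1}]"
                )
            for spot in lane.spots:
                if spot.amplitude > self.background_green:
                    raise ConfigError(
                        f"quench amplitude {spot.amplitude} exceeds background "
                        f"{self.background_green}; spot would clip"
                    )

    @property
    def origin_row(self) -> int:
        return self.height - 1

    @property
    def front_row(self) -> int:
        return 0


@dataclass
class GroundTruthManifest:
    """Per-spot truth for one rendered plate."""

    origin_row: int
    front_row: int
    seed: int
    scale: float  # min-max range of the rendered green plane, [0, 1] units
    spots: pd.DataFrame  # lane, row, col, rf_true, amplitude, sigma_px,
                         # auc_raw, auc_scaled

    def to_json_dict(self) -> dict:
        return {
            "origin_row": self.origin_row,
            "front_row": self.front_row,
            "seed": self.seed,
            "scale": self.scale,
            "spots": self.spots.to_dict(orient="records"),
        }


def render_plate(spec: SyntheticPlateSpec) -> tuple[PlateImage, GroundTruthManifest]:
    """Render a plate and its ground-truth manifest.

    The green plane is background + gradient - sum of Gaussian quench spots
    + noise, clipped to [0, 1] and quantized to 8 bits; red and blue carry a
    low constant level.  Rendering is fully deterministic given the seed.
    """
    h, w = spec.height, spec.width
    rows = np.arange(h, dtype=np.float64)[:, None]
    cols = np.arange(w, dtype=np.float64)[None, :]
    gr, gc = spec.gradient
    green = np.full((h, w), spec.background_green, dtype=np.float64)
    green += gr * (rows / max(h - 1, 1) - 0.5)
    green += gc * (cols / max(w - 1, 1) - 0.5)

    records = []
    dev = spec.origin_row - spec.front_row
    for lane_idx, lane in enumerate(spec.lanes):
        for spot in lane.spots:
            r0 = spec.origin_row - spot.rf_true * dev
            c0 = lane.column_center
            d2 = (rows - r0) ** 2 + (cols - c0) ** 2
            green -= spot.amplitude * np.exp(-d2 / (2.0 * spot.sigma_px ** 2))
            records.append({
                "lane": lane_idx, "row": r0, "col": c0,
                "rf_true": spot.rf_true, "amplitude": spot.amplitude,
                "sigma_px": spot.sigma_px,
                "auc_raw": TWO_PI * spot.amplitude * spot.sigma_px ** 2,
            })

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        green += rng.normal(0.0, spec.noise_sd, size=green.shape)
    g8 = np.clip(np.rint(np.clip(green, 0.0, 1.0) * 255.0), 0, 255).astype(np.uint8)

    gq = g8.astype(np.float64) / 255.0
    scale = float(gq.max() - gq.min())
    spots_df = pd.DataFrame(
        records, columns=["lane", "row", "col", "rf_true", "amplitude",
                          "sigma_px", "auc_raw"])
    spots_df["auc_scaled"] = (
        spots_df["auc_raw"] / scale if scale > 0 else np.nan)

    pixels = np.empty((h, w, 3), dtype=np.uint8)
    pixels[:, :, 0] = 15
    pixels[:, :, 1] = g8
    pixels[:, :, 2] = 15
    img = PlateImage(pixels=pixels, origin_row=spec.origin_row,
                     front_row=spec.front_row)
    manifest = GroundTruthManifest(origin_row=spec.origin_row,
                                   front_row=spec.front_row, seed=spec.seed,
                                   scale=scale, spots=spots_df)
    return img, manifest


# ---------------------------------------------------------------------------
# assay-shaped layouts
# ---------------------------------------------------------------------------

def _amplitude_for_level(level: float, gain: float, baseline: float,
                         sigma_px: float, background: float) -> float:
    """Quench amplitude whose analytic AUC equals gain*level + baseline."""
    amp = (gain * level + baseline) / (TWO_PI * sigma_px ** 2)
    if amp > background:
        raise ConfigError(
            f"level {level} needs amplitude {amp:.3f} > background {background}; "
            "clipping would corrupt linearity"
        )
    if amp <= 0:
        raise ConfigError(f"level {level} gives non-positive amplitude")
    return amp


def build_assay_spec(
    calib_levels,
    sample_levels=(),
    *,
    gain: float = 30.0,
    baseline: float = 21.0,
    rf_true: float = 0.604,
    sample_rf=None,
    sigma_px: float = 6.0,
    height: int = 400,
    background_green: float = 0.85,
    gradient: tuple[float, float] = (0.0, 0.0),
    noise_sd: float = 0.005,
    lane_spacing: int = 56,
    margin: int = 40,
    seed: int = 0,
) -> tuple[SyntheticPlateSpec, pd.DataFrame]:
    """One plate carrying a standard calibration ladder and sample lanes.

    This mirrors the bench workflow of spotting standards and unknowns side
    by side on the same plate, so the whole-image normalization applied by
    the pipeline is shared between calibration and samples.  Spot amplitudes
    are chosen so each spot's analytic AUC is gain*level + baseline (raw
    green units); the positive baseline plays the role of the positive
    intercept real calibrations show.

    Returns the plate spec plus a lane table with columns
    lane, role ('standard' | 'sample'), level, rf_true, amplitude, auc_raw.
    """
    calib_levels = list(calib_levels)
    sample_levels = list(sample_levels)
    n_lanes = len(calib_levels) + len(sample_levels)
    if n_lanes == 0:
        raise ConfigError("at least one lane is required")
    if sample_rf is None:
        sample_rf = [rf_true] * len(sample_levels)
    if len(sample_rf) != len(sample_levels):
        raise ConfigError("sample_rf must match sample_levels in length")
    width = max(32, 2 * margin + lane_spacing * (n_lanes - 1))
    lanes, rows = [], []
    roles = ([("standard", lv, rf_true) for lv in calib_levels]
             + [("sample", lv, rf) for lv, rf in zip(sample_levels, sample_rf)])
    for i, (role, level, rf) in enumerate(roles):
        amp = _amplitude_for_level(level, gain, baseline, sigma_px, background_green)
        col = margin + i * lane_spacing
        lanes.append(LaneSpec(column_center=col,
                              spots=(SpotSpec(rf_true=rf, amplitude=amp,
                                              sigma_px=sigma_px),)))
        rows.append({"lane": i, "role": role, "level": level, "rf_true": rf,
                     "amplitude": amp,
                     "auc_raw": TWO_PI * amp * sigma_px ** 2})
    spec = SyntheticPlateSpec(width=width, height=height, lanes=tuple(lanes),
                              background_green=background_green,
                              gradient=gradient, noise_sd=noise_sd, seed=seed)
    return spec, pd.DataFrame(rows)


def render_calibration_set(
    levels,
    gain: float,
    template: SyntheticPlateSpec | None = None,
    *,
    baseline: float = 21.0,
    sigma_px: float = 6.0,
    seed: int = 0,
    n_plates: int = 1,
):
    """Render ``n_plates`` replicate plates, each with one lane per level.

    Returns (list of (PlateImage, GroundTruthManifest), truth table).  The
    truth table has one row per rendered spot with its plate index, level and
    analytic AUC in raw and min-max-scaled units.  An empty level list
    yields an empty set without error.
    """
    levels = list(levels)
    if any(lv <= 0 for lv in levels):
        raise ConfigError("levels must be positive")
    if not levels:
        return [], pd.DataFrame(
            columns=["plate", "lane", "level", "amplitude", "auc_raw", "auc_scaled"])
    tmpl = template or SyntheticPlateSpec()
    plates, frames = [], []
    for p in range(n_plates):
        spec, lane_table = build_assay_spec(
            levels, gain=gain, baseline=baseline, sigma_px=sigma_px,
            height=tmpl.height, background_green=tmpl.background_green,
            gradient=tmpl.gradient, noise_sd=tmpl.noise_sd,
            seed=int(seed) + p,
        )
        img, manifest = render_plate(spec)
        plates.append((img, manifest))
        tab = lane_table.copy()
        tab["plate"] = p
        tab["auc_scaled"] = manifest.spots["auc_scaled"].to_numpy()
        frames.append(tab[["plate", "lane", "level", "amplitude",
                           "auc_raw", "auc_scaled"]])
    return plates, pd.concat(frames, ignore_index=True)
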