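"""Calibration, inverse prediction and pharmacopeial verdicts.

A calibration curve relates spot AUC to analyte concentration by ordinary
least squares, AUC = S * conc + b.  Its residual standard deviation Sy
(n - 2 degrees of freedom) and slope S give the detection limits

    LoD = 3.3 * Sy / S        LoQ = 10 * Sy / S

following the ICH signal-to-noise convention.  An unknown's concentration is
the inverse prediction (AUC - b) / S; multiplying by the dilution factor
(mL of working solution equivalent to one tablet) converts it to mg of
active pharmaceutical ingredient (API) per tablet, which is judged against
the pharmacopeial band label_claim * (1 +/- tolerance), 450-550 mg for a
500 mg label at the default 10%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .chromatography import assign_lanes, compute_rf, rf_match, select_principal
from .errors import (ConfigError, InsufficientDataError, InvalidModelError,
                     OutOfCalibrationError)
from .pipeline import PipelineConfig, PlateImage, run_pipeline

__all__ = [
    "CalibrationModel", "QuantConfig", "SampleResult",
    "fit_calibration", "lod_loq", "predict_conc",
    "to_api_content", "content_verdict", "analyze_sample", "analyze_plate",
]


@dataclass
class CalibrationModel:
    """Fitted straight-line calibration AUC = slope * conc + intercept."""

    slope: float
    intercept: float
    r_squared: float
    sy: float                      # residual SD, n - 2 dof
    n_points: int
    linear_range: tuple[float, float]  # (low, high) mg/mL
    lod: float = field(init=False)
    loq: float = field(init=False)

    def __post_init__(self) -> None:
        self.lod, self.loq = lod_loq(self)

    def predict(self, conc) :
        """Forward model: expected AUC at a concentration."""
        return self.slope * np.asarray(conc, dtype=float) + self.intercept

    def to_dict(self) -> dict:
        d = asdict(self)
        d["linear_range"] = list(self.linear_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(slope=float(d["slope"]), intercept=float(d["intercept"]),
                   r_squared=float(d["r_squared"]), sy=float(d["sy"]),
                   n_points=int(d["n_points"]),
                   linear_range=tuple(float(x) for x in d["linear_range"]))


@dataclass
class QuantConfig:
    """Sample-preparation and acceptance parameters.

    The default dilution factor of 125 mL reconstructs the preparation in
    which one tablet is dissolved in 25 mL and the filtrate diluted 5x to the
    4 mg/mL working solution, so conc [mg/mL] * 125 [mL] = mg per tablet.
    """

    dilution_factor_ml: float = 125.0
    label_claim_mg: float = 500.0
    content_tolerance_frac: float = 0.10
    extrapolation_policy: str = "warn"

    def __post_init__(self) -> None:
        if self.dilution_factor_ml <= 0 or self.label_claim_mg <= 0:
            raise ConfigError("dilution factor and label claim must be positive")
        if not (0.0 < self.content_tolerance_frac < 1.0):
            raise ConfigError("content_tolerance_frac must be in (0, 1)")
        if self.extrapolation_policy not in ("warn", "reject"):
            raise ConfigError(f"unknown extrapolation_policy {self.extrapolation_policy!r}")


@dataclass
class SampleResult:
    sample_id: str
    rf: float | None
    rf_ok: bool
    conc_mg_ml: float | None
    api_mg_per_tablet: float | None
    content_ok: bool
    verdict: str  # pass | substandard_content | identity_fail | out_of_calibration

    VERDICTS = ("pass", "substandard_content", "identity_fail", "out_of_calibration")

    def __post_init__(self) -> None:
        if self.verdict not in self.VERDICTS:
            raise ConfigError(f"unknown verdict {self.verdict!r}")
        if (self.verdict == "pass") != (self.rf_ok and self.content_ok):
            raise ConfigError("verdict 'pass' requires rf_ok and content_ok (and vice versa)")


def fit_calibration(concs, aucs) -> CalibrationModel:
    """Ordinary least squares of AUC on concentration.

    Requires at least three paired points with non-degenerate concentration
    spread.  Sy = sqrt(SSE / (n - 2)); the linear range is the span of the
    fitted concentrations.
    """
    x = np.asarray(concs, dtype=float)
    y = np.asarray(aucs, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigError("concs and aucs must be 1-D and the same length")
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"calibration needs >= 3 points, got {n}")
    if np.ptp(x) == 0:
        raise InvalidModelError("zero concentration variance: singular fit")
    res = stats.linregress(x, y)
    fitted = res.intercept + res.slope * x
    sse = float(np.sum((y - fitted) ** 2))
    sy = float(np.sqrt(max(sse, 0.0) / (n - 2)))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0 else 1.0 - sse / sst
    return CalibrationModel(slope=float(res.slope), intercept=float(res.intercept),
                            r_squared=r2, sy=sy, n_points=n,
                            linear_range=(float(x.min()), float(x.max())))


def lod_loq(model: CalibrationModel) -> tuple[float, float]:
    """Detection and quantification limits, 3.3*Sy/S and 10*Sy/S."""
    if model.slope <= 0:
        raise InvalidModelError(f"slope must be > 0, got {model.slope}")
    return 3.3 * model.sy / model.slope, 10.0 * model.sy / model.slope


def predict_conc(model: CalibrationModel, auc: float,
                 policy: str = "warn") -> float:
    """Inverse prediction conc = (AUC - intercept) / slope.

    Outside the calibrated linear range the extrapolation policy applies:
    'warn' extrapolates with a warning, 'reject' raises.  Negative estimates
    are clamped to zero with a warning.
    """
    if model.slope <= 0:
        raise InvalidModelError(f"slope must be > 0, got {model.slope}")
    conc = (float(auc) - model.intercept) / model.slope
    lo, hi = model.linear_range
    eps = 1e-9 * max(1.0, abs(hi))  # keep boundary round-trips from flagging
    if not (lo - eps <= conc <= hi + eps):
        if policy == "reject":
            raise OutOfCalibrationError(
                f"predicted {conc:.4g} mg/mL outside linear range [{lo}, {hi}]"
            )
        warnings.warn(
            f"predicted {conc:.4g} mg/mL outside linear range [{lo}, {hi}]; "
            "extrapolating", stacklevel=2,
        )
    if conc < 0:
        warnings.warn("negative predicted concentration clamped to 0", stacklevel=2)
        conc = 0.0
    return conc


def to_api_content(conc_mg_ml: float, cfg: QuantConfig) -> float:
    """mg of API per tablet = working-solution concentration x dilution factor."""
    if conc_mg_ml < 0:
        raise ConfigError(f"concentration must be >= 0, got {conc_mg_ml}")
    return conc_mg_ml * cfg.dilution_factor_ml


def content_verdict(api_mg: float, cfg: QuantConfig) -> bool:
    """True when the API content is within the pharmacopeial band
    label_claim * (1 +/- tolerance), boundaries inclusive."""
    if api_mg < 0:
        raise ConfigError(f"API content must be >= 0, got {api_mg}")
    lo = cfg.label_claim_mg * (1.0 - cfg.content_tolerance_frac)
    hi = cfg.label_claim_mg * (1.0 + cfg.content_tolerance_frac)
    return lo <= api_mg <= hi


def _verdict(rf_ok: bool, content_ok: bool, out_of_cal: bool) -> str:
    if not rf_ok:
        return "identity_fail"
    if out_of_cal:
        return "out_of_calibration"
    return "pass" if content_ok else "substandard_content"


def analyze_plate(
    img: PlateImage,
    model: CalibrationModel,
    standard_rf: float,
    pipe_cfg: PipelineConfig | None = None,
    quant_cfg: QuantConfig | None = None,
    expected_lanes: int | None = None,
    sample_lanes: list[int] | None = None,
    rf_tolerance_frac: float = 0.10,
    sample_ids: list[str] | None = None,
) -> list[SampleResult]:
    """Run the full chain on a plate and produce one result per sample lane.

    Lanes are clustered from the detected spot columns; ``sample_lanes``
    restricts scoring to those lane indices (all lanes by default, e.g. when
    standards live on a separate plate).  A lane with no detected spot cannot
    be produced by the clustering, so an entirely empty plate yields a single
    identity_fail record.
    """
    pipe_cfg = pipe_cfg or PipelineConfig()
    quant_cfg = quant_cfg or QuantConfig()
    spots, stages = run_pipeline(img, pipe_cfg)
    plate = stages["plate"]
    results: list[SampleResult] = []

    def _sid(i: int) -> str:
        if sample_ids is not None and i < len(sample_ids):
            return sample_ids[i]
        return f"lane{i}"

    if not spots:
        return [SampleResult(sample_id=_sid(0), rf=None, rf_ok=False,
                             conc_mg_ml=None, api_mg_per_tablet=None,
                             content_ok=False, verdict="identity_fail")]

    width = plate.pixels.shape[1]
    n_lanes_guess = expected_lanes or max(len(spots), 1)
    gap = width / (2.0 * n_lanes_guess)
    lane_map = assign_lanes(spots, gap)
    lane_groups = lane_map.lanes(spots)
    chosen = range(len(lane_groups)) if sample_lanes is None else sample_lanes

    for k, lane_idx in enumerate(chosen):
        if lane_idx >= len(lane_groups) or not lane_groups[lane_idx]:
            results.append(SampleResult(sample_id=_sid(k), rf=None, rf_ok=False,
                                        conc_mg_ml=None, api_mg_per_tablet=None,
                                        content_ok=False, verdict="identity_fail"))
            continue
        principal = select_principal(lane_groups[lane_idx])
        rf_res = compute_rf(principal, plate.origin_row, plate.front_row)
        rf_ok = rf_match(rf_res.rf, standard_rf, rf_tolerance_frac)
        out_of_cal = False
        try:
            conc = predict_conc(model, principal.auc,
                                policy=quant_cfg.extrapolation_policy)
        except OutOfCalibrationError:
            out_of_cal = True
            conc = None
        if conc is None:
            api, content_ok = None, False
        else:
            api = to_api_content(conc, quant_cfg)
            content_ok = content_verdict(api, quant_cfg)
        results.append(SampleResult(
            sample_id=_sid(k), rf=rf_res.rf, rf_ok=rf_ok,
            conc_mg_ml=conc, api_mg_per_tablet=api, content_ok=content_ok,
            verdict=_verdict(rf_ok, content_ok, out_of_cal),
        ))
    return results


def analyze_sample(
    img: PlateImage,
    model: CalibrationModel,
    standard_rf: float,
    pipe_cfg: PipelineConfig | None = None,
    quant_cfg: QuantConfig | None = None,
    sample_lane: int = 0,
    expected_lanes: int | None = None,
    rf_tolerance_frac: float = 0.10,
    sample_id: str = "sample",
) -> SampleResult:
    """Single-sample convenience wrapper around :func:`analyze_plate`."""
    return analyze_plate(
        img, model, standard_rf, pipe_cfg, quant_cfg,
        expected_lanes=expected_lanes, sample_lanes=[sample_lane],
        rf_tolerance_frac=rf_tolerance_frac, sample_ids=[sample_id],
    )[0]
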