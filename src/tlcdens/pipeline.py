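"""Pixel-level densitometry chain for UV-quench TLC plate images.

On an F254 silica plate photographed under short-wave UV, the analyte quenches
the green plate fluorescence, so spots are *dark* on a bright green background.
The chain implemented here turns a cropped RGB photograph into a list of
detected spots, each with a densitometric signal (AUC):

    green channel -> invert + min-max normalize -> Gaussian smooth
    -> grayscale dilation -> threshold -> contours -> per-spot AUC

The AUC of each spot is summed on the *pre-blur* inverted-normalized image, so
smoothing and dilation only shape the detection mask, never the quantified
signal.  All geometry is 0-based, row-major, row 0 at the top of the image,
with half-open rectangles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage import measure, transform

from .errors import ConfigError, FormatError, GeometryError

__all__ = [
    "PlateImage",
    "SignalImage",
    "BinaryMask",
    "Spot",
    "PipelineConfig",
    "extract_green",
    "invert_normalize",
    "gaussian_kernel_1d",
    "gaussian_smooth",
    "dilate",
    "otsu_threshold",
    "background_threshold",
    "binarize",
    "spot_auc",
    "detect_spots",
    "resample_to_standard",
    "run_pipeline",
]

THRESHOLD_METHODS = ("background", "otsu", "fixed")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CropRect:
    """Half-open rectangle [top, bottom) x [left, right) in pixel coordinates."""

    top: int
    left: int
    bottom: int
    right: int

    def __post_init__(self) -> None:
        if not (self.top < self.bottom and self.left < self.right):
            raise GeometryError(f"degenerate crop rectangle {self}")

    @property
    def height(self) -> int:
        return self.bottom - self.top

    @property
    def width(self) -> int:
        return self.right - self.left


@dataclass
class PlateImage:
    """An 8-bit RGB plate photograph plus the geometry tying pixel rows to
    the chromatographic axes.

    ``origin_row`` is the row of the sample-application (origin) line and
    ``front_row`` the row reached by the solvent front.  Migration is upward,
    so ``front_row < origin_row``.  The crop runs from the solvent front (top
    boundary row) to the origin line (bottom boundary row).
    """

    pixels: np.ndarray
    origin_row: int
    front_row: int
    crop: CropRect | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise FormatError(
                f"expected H x W x 3 RGB raster, got shape {px.shape}"
            )
        if px.dtype != np.uint8:
            if np.issubdtype(px.dtype, np.integer) and px.min() >= 0 and px.max() <= 255:
                px = px.astype(np.uint8)
            else:
                raise FormatError(f"expected 8-bit channels, got dtype {px.dtype}")
        if px.shape[0] < 32 or px.shape[1] < 32:
            raise FormatError(f"image too small: {px.shape[0]}x{px.shape[1]} (min 32x32)")
        self.pixels = px
        if self.crop is None:
            self.crop = CropRect(self.front_row, 0, self.origin_row + 1, px.shape[1])
        if not (self.front_row < self.origin_row):
            raise GeometryError(
                f"front_row ({self.front_row}) must be above origin_row ({self.origin_row})"
            )
        if self.crop.top != self.front_row or self.crop.bottom - 1 != self.origin_row:
            raise GeometryError(
                "crop must be bounded by the solvent front (top row) and the "
                f"origin line (bottom row); got crop {self.crop}, "
                f"front_row {self.front_row}, origin_row {self.origin_row}"
            )
        if not (0 <= self.crop.top and self.crop.bottom <= px.shape[0]
                and 0 <= self.crop.left and self.crop.right <= px.shape[1]):
            raise GeometryError(f"crop {self.crop} exceeds image bounds {px.shape[:2]}")

    @property
    def cropped_pixels(self) -> np.ndarray:
        c = self.crop
        return self.pixels[c.top:c.bottom, c.left:c.right]

    @property
    def development_height(self) -> int:
        """Rows from solvent front to origin line, inclusive span."""
        return self.origin_row - self.front_row


@dataclass
class SignalImage:
    """Single-channel real-valued image with values in [0, 1]."""

    values: np.ndarray
    provenance: str

    _PROVENANCES = ("green", "inverted_normalized", "smoothed", "dilated")

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise FormatError(f"SignalImage must be 2-D, got shape {v.shape}")
        if v.size and (v.min() < -1e-12 or v.max() > 1 + 1e-12):
            raise FormatError(
                f"SignalImage values out of [0,1]: min={v.min()}, max={v.max()}"
            )
        if self.provenance not in self._PROVENANCES:
            raise ConfigError(f"unknown provenance {self.provenance!r}")
        self.values = np.clip(v, 0.0, 1.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class BinaryMask:
    values: np.ndarray
    threshold_used: float
    method: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if not np.isin(v, (0, 1)).all():
            raise FormatError("BinaryMask values must be exactly 0 or 1")
        if self.method not in THRESHOLD_METHODS:
            raise ConfigError(f"unknown threshold method {self.method!r}")
        self.values = v.astype(np.uint8)


@dataclass
class Spot:
    """A detected spot: contour geometry plus its densitometric signal.

    ``rf`` and ``lane`` are filled in later by the chromatography layer.
    """

    contour: np.ndarray          # (N, 2) closed boundary, (row, col)
    centroid: tuple[float, float]  # (row, col) from image moments
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col) half-open
    area_px: int
    auc: float
    rf: float | None = None
    lane: int | None = None

    def __post_init__(self) -> None:
        r, c = self.centroid
        mr, mc, xr, xc = self.bbox
        if not (mr - 0.5 <= r <= xr - 0.5 and mc - 0.5 <= c <= xc - 0.5):
            raise GeometryError(f"centroid {self.centroid} outside bbox {self.bbox}")
        if self.auc < 0:
            raise GeometryError(f"negative AUC {self.auc}")


@dataclass
class PipelineConfig:
    """Tunable knobs of the detection chain.

    min_spot_area is specified at the reference crop height (standard_height
    rows) and scales with (height / standard_height)^2 so the same physical
    spot size survives resampling.
    """

    blur_kernel: int = 5
    sigma: float = 0.0            # 0 -> derived from kernel width
    dilation_kernel: int = 16
    threshold_method: str = "background"
    fixed_threshold: float | None = None
    background_k: float = 6.0     # sigma-clip factor of the background method
    background_mode: str = "none"  # per-spot AUC baseline: none | annular
    min_spot_area: int = 50
    standard_height: int = 400
    dilate_before_threshold: bool = True

    def __post_init__(self) -> None:
        if self.blur_kernel < 3 or self.blur_kernel % 2 == 0:
            raise ConfigError(f"blur_kernel must be odd and >= 3, got {self.blur_kernel}")
        if self.sigma < 0:
            raise ConfigError(f"sigma must be >= 0, got {self.sigma}")
        if self.dilation_kernel < 1:
            raise ConfigError(f"dilation_kernel must be >= 1, got {self.dilation_kernel}")
        if self.threshold_method not in THRESHOLD_METHODS:
            raise ConfigError(f"unknown threshold_method {self.threshold_method!r}")
        if self.threshold_method == "fixed":
            if self.fixed_threshold is None or not (0.0 <= self.fixed_threshold <= 1.0):
                raise ConfigError("fixed threshold_method requires fixed_threshold in [0,1]")
        elif self.fixed_threshold is not None:
            raise ConfigError("fixed_threshold is only valid with threshold_method='fixed'")
        if self.background_k <= 0:
            raise ConfigError(f"background_k must be > 0, got {self.background_k}")
        if self.background_mode not in ("none", "annular"):
            raise ConfigError(f"unknown background_mode {self.background_mode!r}")
        if self.min_spot_area < 0 or self.standard_height < 32:
            raise ConfigError("min_spot_area must be >= 0 and standard_height >= 32")

    def scaled_min_area(self, height: int) -> float:
        return self.min_spot_area * (height / self.standard_height) ** 2


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def extract_green(img: PlateImage) -> SignalImage:
    """Green-channel plane of the cropped plate, scaled to [0, 1] by /255."""
    return SignalImage(img.cropped_pixels[:, :, 1].astype(np.float64) / 255.0, "green")


def invert_normalize(sig: SignalImage) -> SignalImage:
    """Min-max inversion: out = (max - v) / (max - min).

    Dark quench spots become high signal.  A constant (flat) image would
    divide by zero, so it maps to all-zeros with a warning instead.
    """
    v = sig.values
    vmin, vmax = float(v.min()), float(v.max())
    if vmax == vmin:
        warnings.warn("flat image: min == max, inversion returns zeros", stacklevel=2)
        return SignalImage(np.zeros_like(v), "inverted_normalized")
    return SignalImage((vmax - v) / (vmax - vmin), "inverted_normalized")


def gaussian_kernel_1d(ksize: int, sigma: float = 0.0) -> np.ndarray:
    """Sampled, sum-normalized 1-D Gaussian kernel.

    When sigma <= 0 it is derived from the kernel width as
    sigma = 0.3 * ((ksize - 1)/2 - 1) + 0.8 (so a 5-tap kernel uses 1.1),
    the derivation convention of mainstream imaging toolkits.
    """
    if ksize < 1 or ksize % 2 == 0:
        raise ConfigError(f"kernel size must be odd and >= 1, got {ksize}")
    if sigma <= 0:
        sigma = 0.3 * ((ksize - 1) / 2 - 1) + 0.8
    x = np.arange(ksize, dtype=np.float64) - (ksize - 1) / 2
    w = np.exp(-(x ** 2) / (2.0 * sigma ** 2))
    return w / w.sum()


def gaussian_smooth(sig: SignalImage, cfg: PipelineConfig) -> SignalImage:
    """Separable Gaussian blur with reflected borders and unit DC gain."""
    k = gaussian_kernel_1d(cfg.blur_kernel, cfg.sigma)
    out = ndimage.correlate1d(sig.values, k, axis=0, mode="mirror")
    out = ndimage.correlate1d(out, k, axis=1, mode="mirror")
    return SignalImage(np.clip(out, 0.0, 1.0), "smoothed")


def dilate(sig: SignalImage, cfg: PipelineConfig) -> SignalImage:
    """Grayscale dilation: moving-window maximum over a k x k rectangle.

    For an even kernel (the default 16 x 16) the window spans offsets
    [-k/2, k/2 - 1] around each pixel; borders are replicated.
    """
    out = ndimage.maximum_filter(sig.values, size=cfg.dilation_kernel, mode="nearest")
    return SignalImage(out, "dilated")


def otsu_threshold(values: np.ndarray, n_candidates: int = 256) -> float:
    """Threshold maximizing between-class variance over evenly spaced candidates.

    Candidates are i/(n_candidates - 1) for i = 0..n_candidates-1 on the [0, 1]
    signal scale; the foreground class is v >= t.  Ties go to the smallest
    threshold.  Returns 1.0 (empty foreground for sub-unity images) when the
    image is flat.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        raise FormatError("cannot threshold an empty image")
    if float(v.max()) == float(v.min()):
        warnings.warn("flat image: Otsu undefined, falling back to t = 1.0", stacklevel=2)
        return 1.0
    order = np.sort(v)
    csum = np.concatenate(([0.0], np.cumsum(order)))
    n = v.size
    total = csum[-1]
    candidates = np.linspace(0.0, 1.0, n_candidates)
    # index of first element >= t  ->  background count
    n_bg = np.searchsorted(order, candidates, side="left")
    n_fg = n - n_bg
    valid = (n_bg > 0) & (n_fg > 0)
    sum_bg = csum[n_bg]
    with np.errstate(divide="ignore", invalid="ignore"):
        mu_bg = sum_bg / n_bg
        mu_fg = (total - sum_bg) / n_fg
        var_between = (n_bg / n) * (n_fg / n) * (mu_bg - mu_fg) ** 2
    var_between[~valid] = -np.inf
    return float(candidates[int(np.argmax(var_between))])


def background_threshold(values: np.ndarray, k: float = 6.0) -> float:
    """Robust background sigma-clipping threshold: median + k * sigma_hat.

    sigma_hat is the MAD-based robust standard deviation (1.4826 * MAD) of
    the image, which on a mostly-background plate estimates the background
    noise level regardless of how many spots are present or how bright they
    are.  On effectively noiseless (quantization-limited) images sigma_hat
    collapses to zero, so the clip distance is floored at four 8-bit
    quantization steps to keep the faint quantized tails of neighbouring
    spots from bridging into one component.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise FormatError("cannot threshold an empty image")
    if float(v.max()) == float(v.min()):
        warnings.warn("flat image: threshold undefined, falling back to t = 1.0",
                      stacklevel=2)
        return 1.0
    med = float(np.median(v))
    sigma_hat = 1.4826 * float(np.median(np.abs(v - med)))
    return med + max(k * sigma_hat, 4.0 / 255.0)


def binarize(sig: SignalImage, cfg: PipelineConfig) -> BinaryMask:
    """Inclusive threshold: mask = 1 where signal >= t, else 0.

    The default 'background' method clips at the robust background noise
    level so faint spots survive next to strong ones; 'otsu' maximizes
    between-class variance (best for plates whose spots share similar
    intensity); 'fixed' uses a user-supplied threshold on the [0, 1] scale.
    """
    if cfg.threshold_method == "fixed":
        t = float(cfg.fixed_threshold)
    elif cfg.threshold_method == "otsu":
        t = otsu_threshold(sig.values)
    else:
        t = background_threshold(sig.values, cfg.background_k)
    return BinaryMask((sig.values >= t).astype(np.uint8), t, cfg.threshold_method)


def spot_auc(signal: SignalImage, region: np.ndarray) -> float:
    """Summed signal over the filled region of a contour.

    ``region`` is either a boolean mask of the signal's shape or an (N, 2)
    integer array of (row, col) pixel coordinates.  No background subtraction
    is applied; any uniform baseline is absorbed by the calibration intercept.
    """
    v = signal.values
    region = np.asarray(region)
    if region.dtype == bool:
        if region.shape != v.shape:
            raise GeometryError(
                f"region mask shape {region.shape} != signal shape {v.shape}"
            )
        if not region.any():
            raise GeometryError("empty region")
        return float(v[region].sum())
    if region.ndim != 2 or region.shape[1] != 2 or region.shape[0] == 0:
        raise GeometryError("region must be a boolean mask or non-empty (N, 2) coords")
    rows, cols = region[:, 0], region[:, 1]
    if (rows.min() < 0 or cols.min() < 0
            or rows.max() >= v.shape[0] or cols.max() >= v.shape[1]):
        raise GeometryError("region coordinates outside image bounds")
    return float(v[rows, cols].sum())


def annular_background(signal: SignalImage, rows: np.ndarray, cols: np.ndarray,
                       margin: int = 6) -> float:
    """Median signal in a rectangular annulus around a spot's pixels.

    The annulus is the bounding box expanded by ``margin`` pixels minus the
    spot pixels themselves (clipped at the image border).  Used by the
    optional per-spot baseline subtraction; the median makes it robust to a
    neighbouring spot's tail intruding into the ring.
    """
    h, w = signal.shape
    r0 = max(int(rows.min()) - margin, 0)
    r1 = min(int(rows.max()) + margin + 1, h)
    c0 = max(int(cols.min()) - margin, 0)
    c1 = min(int(cols.max()) + margin + 1, w)
    window = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    window[rows - r0, cols - c0] = True
    ring = ~window
    if not ring.any():
        return 0.0
    return float(np.median(signal.values[r0:r1, c0:c1][ring]))


def _component_contour(filled: np.ndarray, offset: tuple[int, int]) -> np.ndarray:
    """Closed outer boundary of a filled component, in full-image coordinates."""
    padded = np.pad(filled.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    contour = max(contours, key=len)  # outer boundary is the longest
    return contour - 1.0 + np.asarray(offset, dtype=float)


def detect_spots(mask: BinaryMask, signal: SignalImage, cfg: PipelineConfig) -> list[Spot]:
    """External contours of 8-connected foreground components.

    Components smaller (after hole filling) than the height-scaled minimum
    area are discarded as noise.  Centroids come from the image moments of the
    filled component; the AUC is summed over the filled component on the
    supplied inverted-normalized signal.  Spots are returned sorted by
    centroid column, then row.
    """
    if mask.values.shape != signal.shape:
        raise GeometryError(
            f"mask shape {mask.values.shape} != signal shape {signal.shape}"
        )
    if signal.provenance != "inverted_normalized":
        raise ConfigError(
            "AUC must be quantified on the inverted-normalized green image, "
            f"got provenance {signal.provenance!r}"
        )
    labels = measure.label(mask.values, connectivity=2)
    min_area = cfg.scaled_min_area(signal.shape[0])
    spots: list[Spot] = []
    for prop in measure.regionprops(labels):
        filled = prop.image_filled
        area = int(filled.sum())
        if area < min_area:
            continue
        r0, c0, r1, c1 = prop.bbox
        local_r, local_c = np.nonzero(filled)
        rows = local_r + r0
        cols = local_c + c0
        centroid = (float(rows.mean()), float(cols.mean()))
        auc = spot_auc(signal, np.column_stack([rows, cols]))
        if cfg.background_mode == "annular":
            auc = max(auc - annular_background(signal, rows, cols) * area, 0.0)
        contour = _component_contour(filled, (r0, c0))
        spots.append(Spot(contour=contour, centroid=centroid,
                          bbox=(r0, c0, r1, c1), area_px=area, auc=auc))
    spots.sort(key=lambda s: (s.centroid[1], s.centroid[0]))
    return spots


# ---------------------------------------------------------------------------
# chain
# ---------------------------------------------------------------------------

def resample_to_standard(img: PlateImage, cfg: PipelineConfig) -> PlateImage:
    """Resample the crop to ``standard_height`` rows, preserving aspect ratio.

    The calibration response depends on the crop's pixel scale, so every crop
    is brought to a common height before processing; the solvent front maps to
    row 0 and the origin line to the last row.
    """
    cropped = img.cropped_pixels
    h, w = cropped.shape[:2]
    if h == cfg.standard_height:
        out = cropped
    else:
        new_w = max(32, round(w * cfg.standard_height / h))
        resized = transform.resize(
            cropped, (cfg.standard_height, new_w, 3),
            order=1, mode="edge", anti_aliasing=h > cfg.standard_height,
            preserve_range=True,
        )
        out = np.clip(np.rint(resized), 0, 255).astype(np.uint8)
    return PlateImage(pixels=out, origin_row=out.shape[0] - 1, front_row=0)


def run_pipeline(
    img: PlateImage, cfg: PipelineConfig | None = None
) -> tuple[list[Spot], dict]:
    """Full chain from plate photograph to detected spots.

    Returns the spot list plus a dict of intermediate stages (resampled
    plate, each SignalImage, the BinaryMask) for diagnostics.
    """
    cfg = cfg or PipelineConfig()
    plate = resample_to_standard(img, cfg)
    green = extract_green(plate)
    inverted = invert_normalize(green)
    smoothed = gaussian_smooth(inverted, cfg)
    if cfg.dilate_before_threshold:
        dilated = dilate(smoothed, cfg)
        mask = binarize(dilated, cfg)
    else:
        mask = binarize(smoothed, cfg)
        dilated = SignalImage(
            ndimage.maximum_filter(
                mask.values.astype(np.float64), size=cfg.dilation_kernel, mode="nearest"
            ),
            "dilated",
        )
        mask = BinaryMask(dilated.values.astype(np.uint8), mask.threshold_used, mask.method)
    spots = detect_spots(mask, inverted, cfg)
    stages = {
        "plate": plate,
        "green": green,
        "inverted": inverted,
        "smoothed": smoothed,
        "dilated": dilated,
        "mask": mask,
    }
    return spots, stages
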