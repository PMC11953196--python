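"""En-face raster segmentation of the hole, lumen, and photoreceptor annulus.

The published protocol was manual (two graders with a caliper-free tool); this
module implements an automated stand-in with the same three-step structure:
segment the full hole region bounded by the bright circumferential ring,
segment the dark lumen inside it, and take the set difference as the
photoreceptor annulus. All operator parameters are exposed and logged.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage as ndi
from skimage.filters import gaussian
from skimage.measure import label
from skimage.morphology import closing, disk

from .index import AreaSet, compute_pra

__all__ = [
    "EnFaceImage",
    "SegmentationParams",
    "SegmentationResult",
    "SegmentationError",
    "segment_total_area",
    "segment_lumen",
    "mask_area",
    "measure_eye",
    "load_image",
    "save_image",
    "load_mask",
    "save_mask",
]


class SegmentationError(RuntimeError):
    """Raised when a segmentation stage cannot produce a valid mask."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"segmentation failed at stage '{stage}': {message}")


@dataclass(frozen=True)
class EnFaceImage:
    """Single-channel en-face raster with its physical field size.

    ``pixels`` are float intensities rescaled to [0, 1] on load; the field
    defaults to the 3 mm × 3 mm en-face scan pattern. Pixels are assumed
    square to within 1%.
    """

    pixels: np.ndarray
    field_width_mm: float = 3.0
    field_height_mm: float = 3.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("raster must be a non-empty 2-D array")
        if not (self.field_width_mm > 0 and self.field_height_mm > 0):
            raise ValueError("physical field dimensions must be positive")
        object.__setattr__(self, "pixels", px)
        pw, ph = self.pixel_width_mm, self.pixel_height_mm
        if abs(pw - ph) / pw >= 0.01:
            raise ValueError(
                f"non-square pixels: {pw:.5f} x {ph:.5f} mm (tolerance 1%)"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def pixel_width_mm(self) -> float:
        return self.field_width_mm / self.pixels.shape[1]

    @property
    def pixel_height_mm(self) -> float:
        return self.field_height_mm / self.pixels.shape[0]


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable operator chain parameters (defaults logged with every run)."""

    blur_sigma_px: float = 1.0
    closing_radius_px: int = 3
    min_component_px: int = 100
    min_lumen_px: int = 25
    min_lumen_contrast: float = 0.3


@dataclass(frozen=True)
class SegmentationResult:
    total_mask: np.ndarray
    lumen_mask: np.ndarray
    photoreceptor_mask: np.ndarray
    area_set: AreaSet
    params_used: dict = field(default_factory=dict)


def _plateau_midpoint(
    values: np.ndarray, init: float | None = None, max_iter: int = 50
) -> float:
    """Threshold halfway between two intensity plateaus.

    Iterates the midpoint of the class *medians* from a (min+max)/2 start.
    Plain Otsu on these class-imbalanced rasters sits off the midpoint between
    the plateaus, which shifts the blurred boundary crossing and biases areas
    by a fraction of a pixel per edge; class medians are insensitive both to
    the transition pixels that drag class means and to the foreground fraction
    that a fixed quantile would assume.
    """
    if init is None:
        init = 0.5 * (float(values.min()) + float(values.max()))
    t = init
    for _ in range(max_iter):
        lo = values[values < t]
        hi = values[values >= t]
        if lo.size == 0 or hi.size == 0:
            break
        t_new = 0.5 * (float(np.median(lo)) + float(np.median(hi)))
        if abs(t_new - t) < 1e-9:
            break
        t = t_new
    return t


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels = label(mask, connectivity=2)
    if labels.max() == 0:
        return np.zeros_like(mask, dtype=bool)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def _touches_border(mask: np.ndarray) -> bool:
    return bool(
        mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any()
    )


def segment_total_area(
    image: EnFaceImage, params: SegmentationParams | None = None
) -> np.ndarray:
    """Filled region enclosed by (and including) the bright circumferential ring.

    Chain: Gaussian smoothing → plateau-midpoint threshold on the bright
    ring → morphological closing → largest connected component → fill
    enclosed holes.
    Fails when no ring-like structure is found (component under
    ``min_component_px`` or touching the raster border).
    """
    params = params or SegmentationParams()
    px = image.pixels
    if np.ptp(px) == 0:
        raise SegmentationError("total_area", "constant-intensity image, no structure")
    smooth = gaussian(px, sigma=params.blur_sigma_px, preserve_range=True)
    # background dominates the global median, so start the iteration there
    t_bright = _plateau_midpoint(
        smooth.ravel(), init=0.5 * (float(np.median(smooth)) + float(smooth.max()))
    )
    bright = smooth > t_bright
    closed = closing(bright, disk(params.closing_radius_px))
    component = _largest_component(closed)
    n_px = int(component.sum())
    if n_px < params.min_component_px:
        raise SegmentationError(
            "total_area",
            f"largest bright component has {n_px} px "
            f"(< {params.min_component_px}); no ring-like structure",
        )
    if _touches_border(component):
        raise SegmentationError(
            "total_area", "bright component touches the raster border"
        )
    return ndi.binary_fill_holes(component)


def segment_lumen(
    image: EnFaceImage,
    total_mask: np.ndarray,
    params: SegmentationParams | None = None,
) -> np.ndarray:
    """Dark interior region strictly inside the total-area mask.

    Within the mask, thresholds at the plateau midpoint of the masked
    intensities, keeps the largest dark component, and fills holes. Raises
    when the interior has no dark core.
    """
    params = params or SegmentationParams()
    if total_mask.shape != image.pixels.shape:
        raise ValueError("total_mask and image dimensions differ")
    smooth = gaussian(image.pixels, sigma=params.blur_sigma_px, preserve_range=True)
    vals = smooth[total_mask]
    if vals.size == 0:
        raise SegmentationError("lumen", "empty total-area mask")
    t = _plateau_midpoint(vals)
    lo, hi = vals[vals < t], vals[vals >= t]
    separation = (
        float(np.median(hi)) - float(np.median(lo)) if lo.size and hi.size else 0.0
    )
    # a genuine dark core separates the interior plateaus far more than the
    # blurred boundary pixels of an all-bright interior ever do
    if separation < params.min_lumen_contrast:
        raise SegmentationError(
            "lumen",
            f"no lumen detected: interior plateau separation {separation:.3f} "
            f"below {params.min_lumen_contrast}",
        )
    dark = (smooth < t) & total_mask
    component = _largest_component(dark)
    filled = ndi.binary_fill_holes(component) & total_mask
    n_px = int(filled.sum())
    if n_px < params.min_lumen_px:
        raise SegmentationError(
            "lumen", f"no lumen detected: dark core has only {n_px} px"
        )
    return filled


def mask_area(mask: np.ndarray, image: EnFaceImage) -> float:
    """Physical area of a binary mask in mm² (pixel counting, no sub-pixel)."""
    mask = np.asarray(mask)
    if mask.shape != image.pixels.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match image {image.pixels.shape}"
        )
    return float(mask.astype(bool).sum()) * image.pixel_width_mm * image.pixel_height_mm


def measure_eye(
    image: EnFaceImage,
    params: SegmentationParams | None = None,
    total_mask: np.ndarray | None = None,
    lumen_mask: np.ndarray | None = None,
) -> SegmentationResult:
    """Full three-step measurement: hole region → lumen → annulus → areas.

    Precomputed masks may be supplied to mirror a manual grading workflow;
    each omitted mask is produced automatically. Deterministic for a fixed
    image and parameter set.
    """
    params = params or SegmentationParams()
    if total_mask is None:
        total_mask = segment_total_area(image, params)
    else:
        total_mask = np.asarray(total_mask, dtype=bool)
    if lumen_mask is None:
        lumen_mask = segment_lumen(image, total_mask, params)
    else:
        lumen_mask = np.asarray(lumen_mask, dtype=bool)
        if (lumen_mask & ~total_mask).any():
            raise SegmentationError("lumen", "supplied lumen mask leaves the total mask")
    photoreceptor_mask = total_mask & ~lumen_mask
    ta = mask_area(total_mask, image)
    la = mask_area(lumen_mask, image)
    return SegmentationResult(
        total_mask=total_mask,
        lumen_mask=lumen_mask,
        photoreceptor_mask=photoreceptor_mask,
        area_set=compute_pra(ta, la),
        params_used=asdict(params),
    )


# --- raster I/O -------------------------------------------------------------


def load_image(
    path: str | Path, field_width_mm: float = 3.0, field_height_mm: float = 3.0
) -> EnFaceImage:
    """Read a single-channel PNG/TIFF and rescale intensities to [0, 1]."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = np.asarray(tifffile.imread(path))
    else:
        with Image.open(path) as im:
            arr = np.asarray(im.convert("I") if im.mode not in ("L", "I;16", "I") else im)
    if arr.ndim == 3:
        arr = arr[..., 0]
    # rescale to [0,1] by the nominal range of the storage dtype
    if arr.dtype == np.uint8:
        arr = arr.astype(float) / 255.0
    elif arr.dtype in (np.uint16, np.int32):
        arr = arr.astype(float) / 65535.0
    else:
        arr = arr.astype(float)
        if arr.max() > 1.0:
            arr = arr / (65535.0 if arr.max() > 255.0 else 255.0)
    return EnFaceImage(
        pixels=np.clip(arr, 0.0, 1.0),
        field_width_mm=field_width_mm,
        field_height_mm=field_height_mm,
    )


def save_image(image: EnFaceImage, path: str | Path, bit_depth: int = 8) -> None:
    """Write the raster as 8-bit PNG or 16-bit TIFF (by extension/bit depth)."""
    path = Path(path)
    px = np.clip(image.pixels, 0.0, 1.0)
    if bit_depth == 16 or path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, np.round(px * 65535).astype(np.uint16))
    else:
        Image.fromarray(np.round(px * 255).astype(np.uint8), mode="L").save(path)


def load_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask raster (foreground = maximum value)."""
    img = load_image(path)
    return img.pixels >= 0.5


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8), mode="L").save(Path(path))
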