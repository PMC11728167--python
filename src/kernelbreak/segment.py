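"""Scene segmentation: background subtraction, gray-level thresholding and
connected-component extraction into per-kernel masks.

Kernels are presented on a uniform tray background, so segmentation is a
global threshold (Otsu or fixed) followed by 4-connected component
labelling; touching kernels are not split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure
from skimage.filters import threshold_otsu


class SegmentationError(ValueError):
    pass


@dataclass(frozen=True)
class KernelMask:
    """Tight-cropped binary silhouette of one kernel within a parent scene.

    ``offset`` is the (row, col) of the crop origin in the scene, 0-based;
    the bounding box is half-open: ``[row0, row1) x [col0, col1)``.
    """

    pixels: np.ndarray
    offset: tuple[int, int] = (0, 0)
    scene_id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "pixels", np.asarray(self.pixels).astype(bool))

    @property
    def area(self) -> int:
        return int(self.pixels.sum())

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        r0, c0 = self.offset
        return (r0, c0, r0 + self.pixels.shape[0], c0 + self.pixels.shape[1])


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """RGB -> gray by the standard luminance weighting; gray passes through."""
    image = np.asarray(image)
    if image.ndim == 2:
        return image.astype(float)
    if image.ndim == 3 and image.shape[-1] in (3, 4):
        rgb = image[..., :3].astype(float)
        return rgb @ np.array([0.2125, 0.7154, 0.0721])
    raise SegmentationError(f"unsupported image shape {image.shape}")


def subtract_background(image: np.ndarray, background: np.ndarray) -> np.ndarray:
    """Pixelwise absolute difference |image - background|, clipped to [0, 255]."""
    image = to_grayscale(image)
    background = to_grayscale(background)
    if image.shape != background.shape:
        raise SegmentationError(
            f"shape mismatch: image {image.shape} vs background {background.shape}"
        )
    return np.clip(np.abs(image - background), 0, 255)


def threshold_segment(image: np.ndarray, method: str = "otsu", t: float | None = None) -> np.ndarray:
    """Binarize a gray image; foreground = pixels >= threshold.

    ``method`` is ``"otsu"`` or ``"fixed"`` (with threshold ``t``).  On a
    bimodal two-level image Otsu's threshold lies strictly between the two
    levels; a constant image has no threshold and raises.
    """
    image = to_grayscale(image)
    if image.size == 0:
        raise SegmentationError("empty image")
    if method == "otsu":
        if np.ptp(image) == 0:
            raise SegmentationError("constant image: Otsu threshold undefined")
        thr = float(threshold_otsu(image))
        lo, hi = image.min(), image.max()
        if not lo < thr:  # skimage returns a bin edge; nudge off the minimum
            thr = np.nextafter(lo, hi)
    elif method == "fixed":
        if t is None:
            raise SegmentationError("fixed thresholding requires t")
        thr = float(t)
    else:
        raise SegmentationError(f"unknown threshold method {method!r}")
    return image >= thr


def extract_components(
    mask: np.ndarray, min_area: int = 50, scene_id: str | None = None
) -> list[KernelMask]:
    """Split a binary raster into tight-cropped 4-connected components.

    Components smaller than ``min_area`` px^2 are discarded (noise specks).
    Masks are returned row-major by bounding-box origin, deterministically.
    """
    if min_area < 1:
        raise SegmentationError("min_area must be >= 1")
    mask = np.asarray(mask).astype(bool)
    labels = measure.label(mask, connectivity=1)
    out: list[tuple[tuple[int, int], KernelMask]] = []
    for region in measure.regionprops(labels):
        if region.area < min_area:
            continue
        r0, c0, r1, c1 = region.bbox
        out.append(
            ((r0, c0), KernelMask(pixels=region.image, offset=(r0, c0), scene_id=scene_id))
        )
    out.sort(key=lambda item: item[0])
    return [m for _, m in out]


def segment_scene(
    image: np.ndarray,
    background: np.ndarray | None = None,
    method: str = "otsu",
    t: float | None = None,
    min_area: int = 50,
    scene_id: str | None = None,
) -> list[KernelMask]:
    """Full segmentation pipeline: (optional background subtraction) ->
    threshold -> component extraction."""
    gray = subtract_background(image, background) if background is not None else to_grayscale(image)
    binary = threshold_segment(gray, method=method, t=t)
    return extract_components(binary, min_area=min_area, scene_id=scene_id)


def components_table(masks: list[KernelMask]) -> pd.DataFrame:
    """CSV-ready table of component bounding boxes (0-based, half-open)."""
    rows = []
    for k, m in enumerate(masks):
        r0, c0, r1, c1 = m.bbox
        rows.append(
            {
                "kernel_id": k,
                "scene_id": m.scene_id if m.scene_id is not None else "",
                "bbox_row0": r0,
                "bbox_col0": c0,
                "bbox_row1": r1,
                "bbox_col1": c1,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["kernel_id", "scene_id", "bbox_row0", "bbox_col0", "bbox_row1", "bbox_col1"],
    )
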