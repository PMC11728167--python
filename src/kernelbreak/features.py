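"""The seven kernel shape descriptors.

For a kernel silhouette the descriptors are: area ``S``, perimeter ``C``,
aspect ratio ``R_a = L_ab / L_cd``, long axis ``L_ab`` (farthest boundary
pair), short axis ``L_cd`` (silhouette extent through the centroid,
perpendicular to the long axis), circularity ``e = S / S_2`` and
rectangularity ``R_r = S / S_1``, where ``S_2`` and ``S_1`` are the areas of
the minimum circumscribed circle and the minimum (rotated) circumscribed
rectangle.  Ratios are computed from the unscaled pixel geometry and are
therefore scale-free; ``S``, ``C``, ``L_ab``, ``L_cd`` are reported in mm
units when a mm/px scale is given, else in pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from . import geometry
from .geometry import GeometryError

#: canonical feature order used in every table and model schema
FEATURE_NAMES = ("S", "C", "R_a", "L_ab", "L_cd", "e", "R_r")


@dataclass(frozen=True)
class FeatureVector:
    """Seven shape descriptors of one kernel silhouette."""

    S: float
    C: float
    R_a: float
    L_ab: float
    L_cd: float
    e: float
    R_r: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"feature {f.name}={v!r} must be finite and positive")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)

    def as_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in FEATURE_NAMES}


def area_and_perimeter(mask: np.ndarray, polygon: np.ndarray | None = None) -> tuple[float, float]:
    """Area ``S`` (foreground pixel count) and perimeter ``C`` (arc length of
    the traced sub-pixel boundary polygon)."""
    if polygon is None:
        polygon, _ = geometry.boundary_polygon(mask)
    s = float(np.asarray(mask).astype(bool).sum())
    c = geometry.polygon_perimeter(polygon)
    return s, c


def extract_features(mask, scale: float | None = None) -> FeatureVector:
    """Compute the seven descriptors of a single-component mask.

    Parameters
    ----------
    mask
        Binary raster (or a :class:`~kernelbreak.segment.KernelMask`).
    scale
        Optional mm/px factor applied to lengths (and squared for ``S``).
        Dimensionless ratios are unaffected.
    """
    pixels = getattr(mask, "pixels", mask)
    polygon, hull = geometry.boundary_polygon(pixels)
    s, c = area_and_perimeter(pixels, polygon)
    l_ab, l_cd, _, _ = geometry.long_short_axes(pixels, polygon)
    shapes = geometry.enclosing_shapes(hull)
    e = s / shapes.s2
    r_r = s / shapes.s1
    # raster quantization can push a ratio a hair over 1; the descriptors are
    # defined on (0, 1]
    e = min(e, 1.0)
    r_r = min(r_r, 1.0)
    r_a = l_ab / l_cd
    if scale is not None:
        if scale <= 0:
            raise ValueError("scale must be positive mm/px")
        s *= scale**2
        c *= scale
        l_ab *= scale
        l_cd *= scale
    return FeatureVector(S=s, C=c, R_a=r_a, L_ab=l_ab, L_cd=l_cd, e=e, R_r=r_r)


def features_table(masks, scale: float | None = None, ids=None, scene_id=None) -> pd.DataFrame:
    """Feature table for a list of masks (columns in :data:`FEATURE_NAMES` order)."""
    rows = []
    for k, m in enumerate(masks):
        fv = extract_features(m, scale=scale)
        row = {"kernel_id": ids[k] if ids is not None else k}
        if scene_id is not None:
            row["scene_id"] = scene_id
        row.update(fv.as_dict())
        rows.append(row)
    cols = ["kernel_id"] + (["scene_id"] if scene_id is not None else []) + list(FEATURE_NAMES)
    return pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)
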