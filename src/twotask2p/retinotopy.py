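"""Visual-field-sign maps from azimuth/elevation retinotopy.

The field sign at a pixel is the sine of the angle between the spatial
gradients of the elevation and azimuth maps:

    sign = sin(angle(grad elevation) - angle(grad azimuth))

so an identity mapping (azimuth increasing along x, elevation along y) is +1
everywhere, and a mirror-image mapping (elevation reversed) is -1. Sign
reversals mark borders between visual areas. The convention only fixes the
global sign; the spatial pattern of reversals is invariant to it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "RetinotopyMaps",
    "FieldSignMap",
    "field_sign",
    "segment_sign_regions",
]


@dataclass(frozen=True)
class RetinotopyMaps:
    """Azimuth and elevation preference (degrees) on a pixel grid."""

    azimuth: np.ndarray
    elevation: np.ndarray
    pixel_size: float | None = None  # mm/px, optional

    def __post_init__(self) -> None:
        az = np.asarray(self.azimuth, dtype=float)
        el = np.asarray(self.elevation, dtype=float)
        if az.shape != el.shape or az.ndim != 2:
            raise ValueError("azimuth and elevation must be 2-D grids of equal shape")
        if not (np.all(np.isfinite(az)) and np.all(np.isfinite(el))):
            raise ValueError("retinotopy maps must be finite")
        object.__setattr__(self, "azimuth", az)
        object.__setattr__(self, "elevation", el)

    @property
    def shape(self) -> tuple[int, int]:
        return self.azimuth.shape


@dataclass(frozen=True)
class FieldSignMap:
    """Per-pixel field sign in [-1, 1] (NaN where the gradient vanishes),
    plus integer region labels after thresholding (0 = background)."""

    sign: np.ndarray
    region_labels: np.ndarray | None = None
    region_signs: dict[int, int] | None = None


def field_sign(maps: RetinotopyMaps, smooth_sigma_px: float = 2.0) -> FieldSignMap:
    """Compute the visual field sign map.

    Each map is optionally Gaussian-smoothed (``smooth_sigma_px`` pixels,
    reflective boundaries), gradients are taken by central differences
    (one-sided at the borders), and the sign is the sine of the angle between
    the two gradient vectors. Pixels where either gradient vanishes get NaN.
    """
    if maps.shape[0] < 3 or maps.shape[1] < 3:
        raise ValueError("grid must be at least 3x3")
    az, el = maps.azimuth, maps.elevation
    if smooth_sigma_px > 0:
        az = ndimage.gaussian_filter(az, smooth_sigma_px, mode="reflect")
        el = ndimage.gaussian_filter(el, smooth_sigma_px, mode="reflect")
    az_gy, az_gx = np.gradient(az)
    el_gy, el_gx = np.gradient(el)
    ang_az = np.arctan2(az_gy, az_gx)
    ang_el = np.arctan2(el_gy, el_gx)
    sign = np.sin(ang_el - ang_az)
    flat = ((az_gx == 0) & (az_gy == 0)) | ((el_gx == 0) & (el_gy == 0))
    sign = np.where(flat, np.nan, sign)
    return FieldSignMap(sign=sign)


def segment_sign_regions(
    signmap: FieldSignMap, threshold: float = 0.3
) -> FieldSignMap:
    """Threshold a field-sign map into connected signed regions.

    Connected components (4-connectivity) of ``|sign| > threshold`` are
    labeled, positive- and negative-sign pixels separately, and each region
    carries its dominant sign. Returns a new FieldSignMap with
    ``region_labels`` (0 = background) and ``region_signs`` filled in.
    """
    sign = signmap.sign
    valid = np.isfinite(sign)
    pos = valid & (sign > threshold)
    neg = valid & (sign < -threshold)
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-connectivity
    pos_labels, n_pos = ndimage.label(pos, structure=structure)
    neg_labels, n_neg = ndimage.label(neg, structure=structure)
    labels = pos_labels.copy()
    labels[neg_labels > 0] = neg_labels[neg_labels > 0] + n_pos
    region_signs = {i: 1 for i in range(1, n_pos + 1)}
    region_signs.update({i + n_pos: -1 for i in range(1, n_neg + 1)})
    return FieldSignMap(sign=sign, region_labels=labels, region_signs=region_signs)
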