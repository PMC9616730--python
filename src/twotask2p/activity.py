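"""Per-neuron activity statistics from ROI pixel data and deconvolved traces.

The central statistic is the *isolation distance*: how far a cell's pixels sit
from the surrounding neuropil pixels, measured on the first principal component
of the joint pixel x time fluorescence matrix. It behaves like a per-neuron
signal-to-noise ratio — a neuron whose soma pixels carry fluorescence dynamics
beyond the shared background scores high; a silent neuron whose pixels look
like neuropil scores near zero — and is robust to the overall magnitude of the
fluorescence because the underlying Bhattacharyya distance is invariant to a
common rescaling of both pixel-loading distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RoiPixelPatch",
    "ActivitySummary",
    "neuropil_correct",
    "pixel_pc1_loadings",
    "bhattacharyya_gaussian",
    "isolation_distance",
    "mean_rate",
    "classify_active",
]

#: Isolation-distance threshold separating active from inactive neurons.
ACTIVE_THRESHOLD = 0.3

#: Default multiplicative neuropil coefficient (midpoint of the typical
#: per-cell estimates of ~0.6-0.8).
DEFAULT_NEUROPIL_COEFFICIENT = 0.7


@dataclass(frozen=True)
class RoiPixelPatch:
    """Fluorescence of one ROI's cell pixels and its neuropil surround.

    Parameters
    ----------
    cell_pixels : ndarray, shape (n_cell_px, T)
        Fluorescence time series of the pixels assigned to the soma.
    neuropil_pixels : ndarray, shape (n_np_px, T)
        Fluorescence time series of the surrounding neuropil pixels.
    frame_rate : float
        Imaging rate in Hz.
    """

    cell_pixels: np.ndarray
    neuropil_pixels: np.ndarray
    frame_rate: float = 10.0

    def __post_init__(self) -> None:
        cell = np.asarray(self.cell_pixels, dtype=float)
        neu = np.asarray(self.neuropil_pixels, dtype=float)
        if cell.ndim != 2 or neu.ndim != 2:
            raise ValueError("pixel matrices must be 2-D (pixels x time)")
        if cell.shape[0] < 2 or neu.shape[0] < 2:
            raise ValueError("need at least 2 pixels in each compartment")
        if cell.shape[1] != neu.shape[1]:
            raise ValueError(
                f"cell and neuropil pixels must share T "
                f"({cell.shape[1]} != {neu.shape[1]})"
            )
        object.__setattr__(self, "cell_pixels", cell)
        object.__setattr__(self, "neuropil_pixels", neu)

    @property
    def n_frames(self) -> int:
        return self.cell_pixels.shape[1]


@dataclass(frozen=True)
class ActivitySummary:
    """Per-neuron, per-condition activity summary."""

    isolation_distance: float
    mean_rate: float
    active: bool
    neuropil_coefficient: float = DEFAULT_NEUROPIL_COEFFICIENT

    def __post_init__(self) -> None:
        if self.isolation_distance < 0:
            raise ValueError("isolation_distance must be nonnegative")
        if not 0 <= self.neuropil_coefficient <= 1.5:
            raise ValueError("neuropil_coefficient outside [0, 1.5]")


def neuropil_correct(
    cell_trace: np.ndarray,
    neuropil_trace: np.ndarray,
    coefficient: float = DEFAULT_NEUROPIL_COEFFICIENT,
) -> np.ndarray:
    """Subtract a scaled neuropil trace from a cell trace.

    Returns ``cell - coefficient * neuropil`` elementwise.
    """
    cell = np.asarray(cell_trace, dtype=float)
    neu = np.asarray(neuropil_trace, dtype=float)
    if cell.shape != neu.shape:
        raise ValueError("cell and neuropil traces must have equal length")
    if coefficient < 0:
        raise ValueError("neuropil coefficient must be nonnegative")
    return cell - coefficient * neu


def pixel_pc1_loadings(
    patch: RoiPixelPatch, center: str = "timecourse"
) -> tuple[np.ndarray, np.ndarray]:
    """First-principal-component loading of every pixel in a patch.

    Cell and neuropil pixel rows are stacked into one pixels x time matrix.
    With ``center="timecourse"`` (default) the mean time course across all
    stacked pixels is subtracted from every row, so that fluorescence shared
    by cell and surround cancels and only deviations from the common
    background drive the principal component. ``center="per_pixel"`` instead
    removes each pixel's own temporal mean. The matrix is then reduced by SVD
    and each pixel's score on the first component is returned, partitioned
    back into (cell, neuropil) groups.

    The component sign is fixed so that the mean cell loading is >= the mean
    neuropil loading; the downstream distance is sign-invariant, so this only
    standardizes diagnostics.
    """
    stacked = np.vstack([patch.cell_pixels, patch.neuropil_pixels])
    if center == "timecourse":
        stacked = stacked - stacked.mean(axis=0, keepdims=True)
    elif center == "per_pixel":
        stacked = stacked - stacked.mean(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown centering mode: {center!r}")
    if not np.any(stacked):
        raise ValueError("centered pixel matrix is identically zero; "
                         "no principal direction")
    u, s, _ = np.linalg.svd(stacked, full_matrices=False)
    loadings = u[:, 0] * s[0]
    n_cell = patch.cell_pixels.shape[0]
    cell_load, np_load = loadings[:n_cell], loadings[n_cell:]
    if cell_load.mean() < np_load.mean():
        cell_load, np_load = -cell_load, -np_load
    return cell_load, np_load


def bhattacharyya_gaussian(
    mean1: float, var1: float, mean2: float, var2: float
) -> float:
    """Bhattacharyya distance between two univariate Gaussians.

    D = 1/4 (m1-m2)^2 / (v1+v2) + 1/2 ln((v1+v2) / (2 sqrt(v1 v2)))

    Zero iff the distributions are identical; symmetric; invariant to a
    common affine rescaling of both distributions.
    """
    if var1 <= 0 or var2 <= 0:
        raise ValueError("variances must be positive")
    dmean = mean1 - mean2
    vsum = var1 + var2
    return 0.25 * dmean * dmean / vsum + 0.5 * np.log(
        vsum / (2.0 * np.sqrt(var1 * var2))
    )


def isolation_distance(patch: RoiPixelPatch, center: str = "timecourse") -> float:
    """Isolation distance of a cell from its neuropil surround.

    Gaussian Bhattacharyya distance between the empirical (mean, variance)
    of the cell-pixel and neuropil-pixel PC1 loadings.
    """
    cell_load, np_load = pixel_pc1_loadings(patch, center=center)
    return bhattacharyya_gaussian(
        cell_load.mean(),
        cell_load.var(ddof=1),
        np_load.mean(),
        np_load.var(ddof=1),
    )


def mean_rate(trace: np.ndarray) -> float:
    """Mean deconvolved activity per frame of a nonnegative trace."""
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty trace")
    if np.any(trace < 0):
        raise ValueError("deconvolved trace must be nonnegative")
    return float(trace.mean())


def classify_active(
    summary: ActivitySummary, threshold: float = ACTIVE_THRESHOLD
) -> bool:
    """A neuron is active iff its isolation distance strictly exceeds
    ``threshold``."""
    return summary.isolation_distance > threshold
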