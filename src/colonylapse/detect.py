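"""Colony localization on the whole plate.

Colonies may appear at any time during the experiment, so detection runs
on the *temporal sum projection*: every channel of every frame summed per
pixel. The projection is Gaussian-smoothed and fed to a multiscale
Laplacian-of-Gaussian (LoG) blob detector; each blob's scale (standard
deviation sigma) then sizes a square region of interest (ROI) around the
colony for all per-colony downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import blob_log

from colonylapse.stack import Timelapse

__all__ = [
    "ColonyBlob",
    "SquareROI",
    "temporal_sum_projection",
    "smooth_projection",
    "detect_colonies",
    "make_rois",
    "log_response",
]


@dataclass(frozen=True)
class ColonyBlob:
    """A detected colony: integer label, center, Gaussian scale, response.

    Labels are assigned in row-major order of the centers (ties broken by
    column, then by descending detector response), so identical inputs
    always yield identical labels.
    """

    id: int
    center_rc: tuple[float, float]
    sigma: float
    response: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("blob sigma must be positive")


@dataclass(frozen=True)
class SquareROI:
    """Square crop around a colony, sized from the blob's sigma.

    ``half_width = max(1, round(roi_scale * sigma))`` before clipping to
    the image; ``row_range`` / ``col_range`` are half-open pixel
    intervals after clipping.
    """

    colony_id: int
    center_rc: tuple[float, float]
    half_width: int
    row_range: tuple[int, int]
    col_range: tuple[int, int]

    def __post_init__(self) -> None:
        if self.half_width < 1:
            raise ValueError("half_width must be >= 1")
        if self.row_range[0] >= self.row_range[1] or self.col_range[0] >= self.col_range[1]:
            raise ValueError("ROI ranges must be non-empty")

    @property
    def shape(self) -> tuple[int, int]:
        return (
            self.row_range[1] - self.row_range[0],
            self.col_range[1] - self.col_range[0],
        )

    def crop(self, image: np.ndarray) -> np.ndarray:
        """Slice the ROI out of an H x W (or H x W x C) array."""
        return image[
            self.row_range[0] : self.row_range[1],
            self.col_range[0] : self.col_range[1],
        ]


def temporal_sum_projection(stack: Timelapse) -> np.ndarray:
    """Sum all channels of all frames per pixel -> H x W image."""
    return stack.frames.sum(axis=(0, 3))


def smooth_projection(image: np.ndarray, sigma_smooth: float) -> np.ndarray:
    """Gaussian low-pass of a 2-D image; ``sigma_smooth == 0`` is identity."""
    if sigma_smooth < 0:
        raise ValueError("sigma_smooth must be non-negative")
    image = np.asarray(image, dtype=float)
    if sigma_smooth == 0:
        return image
    return ndi.gaussian_filter(image, sigma=sigma_smooth)


def log_response(image: np.ndarray, r: int, c: int, sigma: float) -> float:
    """Scale-normalized negative-LoG response at one pixel.

    ``-sigma^2 (d2/dr2 + d2/dc2) (G_sigma * image)`` evaluated at (r, c);
    positive for bright blobs, maximal over sigma when sigma matches the
    blob scale (for a uniform disc of radius R the maximum sits at
    sigma = R / sqrt(2)).
    """
    filtered = -(sigma**2) * ndi.gaussian_laplace(np.asarray(image, float), sigma)
    return float(filtered[r, c])


def detect_colonies(
    image: np.ndarray,
    min_sigma: float = 3.0,
    max_sigma: float = 30.0,
    n_scales: int = 10,
    threshold: float | None = None,
    threshold_rel: float = 0.05,
    overlap: float = 0.1,
) -> list[ColonyBlob]:
    """Multiscale LoG blob detection on a (smoothed) projection image.

    Scales run logarithmically from *min_sigma* to *max_sigma* in
    *n_scales* steps with per-scale response normalization. *threshold*
    is an absolute response floor; when None it defaults to
    ``threshold_rel * image.max()`` so detection adapts to exposure.
    Overlapping detections are suppressed keeping the stronger response.
    Returns blobs labeled 0..n-1 in row-major center order.
    """
    if not 0 < min_sigma < max_sigma:
        raise ValueError("require 0 < min_sigma < max_sigma")
    image = np.asarray(image, dtype=float)
    peak = image.max() if image.size else 0.0
    if peak <= 0 or np.ptp(image) == 0:
        return []
    if threshold is None:
        threshold = threshold_rel * peak
    if threshold < 0:
        raise ValueError("threshold must be non-negative")

    raw = blob_log(
        image,
        min_sigma=min_sigma,
        max_sigma=max_sigma,
        num_sigma=n_scales,
        threshold=threshold,
        log_scale=True,
        overlap=overlap,
    )
    if raw.size == 0:
        return []

    # blob_log does not report responses; recompute at each detected scale.
    records = []
    for r, c, sigma in raw:
        resp = log_response(image, int(round(r)), int(round(c)), float(sigma))
        records.append((float(r), float(c), float(sigma), resp))
    records.sort(key=lambda b: (b[0], b[1], -b[3]))
    return [
        ColonyBlob(id=i, center_rc=(r, c), sigma=s, response=resp)
        for i, (r, c, s, resp) in enumerate(records)
    ]


def make_rois(
    blobs: list[ColonyBlob],
    roi_scale: float = 3.0,
    image_shape: tuple[int, int] | None = None,
) -> list[SquareROI]:
    """Square ROIs of half-width ``max(1, round(roi_scale * sigma))``.

    A roi_scale of 3 captures ~99.7% of a Gaussian blob's mass. Ranges
    are clipped to *image_shape* when given.
    """
    if roi_scale <= 0:
        raise ValueError("roi_scale must be positive")
    rois = []
    for blob in blobs:
        hw = max(1, round(roi_scale * blob.sigma))
        r0 = int(round(blob.center_rc[0]))
        c0 = int(round(blob.center_rc[1]))
        rows = [r0 - hw, r0 + hw + 1]
        cols = [c0 - hw, c0 + hw + 1]
        if image_shape is not None:
            rows = [max(0, rows[0]), min(image_shape[0], rows[1])]
            cols = [max(0, cols[0]), min(image_shape[1], cols[1])]
        rois.append(
            SquareROI(
                colony_id=blob.id,
                center_rc=blob.center_rc,
                half_width=hw,
                row_range=(rows[0], rows[1]),
                col_range=(cols[0], cols[1]),
            )
        )
    return rois
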