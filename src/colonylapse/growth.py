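"""Per-colony growth quantification.

The colony footprint is approximated by the region expressing fluorescent
signal. Each frame's ROI crop is blob-fit to get a radius, radii become
areas, and the logistic area model

    A(t) = Amax / (1 + exp(-mu_max (t - t0)))

is fit by nonlinear least squares. The specific growth rate
mu(t) = (1/A) dA/dt then has the closed form

    mu(t) = mu_max / (exp(mu_max (t - t0)) + 1),

which decays from mu_max (early, exponential regime) through mu_max/2 at
t0 to 0 at the plateau. Using the closed form avoids numerically
differentiating noisy area data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from scipy.optimize import least_squares, minimize_scalar
from scipy.special import expit
from skimage.feature import blob_log

from colonylapse.detect import SquareROI
from colonylapse.stack import Timelapse

__all__ = [
    "GrowthTrace",
    "GrowthModelFit",
    "Kymograph",
    "logistic_area",
    "radius_series",
    "fit_growth_model",
    "growth_rate_curve",
    "kymograph",
]

#: LoG response of a uniform disc of radius R peaks at sigma = R / sqrt(2),
#: so the estimated radius is sqrt(2) times the fitted blob scale.
SIGMA_TO_RADIUS = math.sqrt(2.0)


@dataclass(frozen=True)
class GrowthTrace:
    """Per-frame colony radius and area; undetected frames hold NaN."""

    colony_id: int
    times: np.ndarray
    radius_px: np.ndarray
    area_px2: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        radius = np.asarray(self.radius_px, dtype=float)
        if times.shape != radius.shape:
            raise ValueError("times and radius_px must have equal length")
        if np.nanmin(radius, initial=0.0) < 0:
            raise ValueError("radii must be non-negative")
        area = np.pi * radius**2
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "radius_px", radius)
        object.__setattr__(self, "area_px2", area)

    @property
    def n_defined(self) -> int:
        return int(np.isfinite(self.radius_px).sum())


@dataclass(frozen=True)
class GrowthModelFit:
    """Fitted logistic area model parameters for one colony."""

    colony_id: int
    Amax: float  # plateau area, px^2
    mu_max: float  # maximal specific growth rate, h^-1
    t0: float  # half-maximum time, h
    residual_rms: float
    n_points_used: int

    def __post_init__(self) -> None:
        if self.Amax <= 0 or self.mu_max <= 0:
            raise ValueError("Amax and mu_max must be positive")
        if self.n_points_used < 4:
            raise ValueError("a growth fit needs at least 4 points")

    def area(self, t: np.ndarray | float) -> np.ndarray | float:
        """Fitted A(t)."""
        return logistic_area(t, self.Amax, self.mu_max, self.t0)

    def radius(self, t: np.ndarray | float) -> np.ndarray | float:
        """Fitted radius curve r(t) = sqrt(A(t) / pi), used for masking."""
        return np.sqrt(self.area(t) / np.pi)


@dataclass(frozen=True)
class Kymograph:
    """Space-time plot of channel-summed intensity along the ROI's central row."""

    colony_id: int
    values: np.ndarray  # T x W_roi
    times: np.ndarray


def logistic_area(t, Amax: float, mu_max: float, t0: float):
    """A(t) = Amax / (1 + exp(-mu_max (t - t0))), overflow-safe."""
    return Amax * expit(mu_max * (np.asarray(t, dtype=float) - t0))


def _log_point_response(
    padded: np.ndarray, r: int, c: int, sigma: float, pad: int
) -> float:
    """Scale-normalized negative-LoG response at one pixel of a padded image.

    Evaluates the correlation of a truncated (4 sigma) LoG kernel with
    the patch around (r, c) directly — equivalent to
    ``-sigma^2 * gaussian_laplace(image, sigma)[r, c]`` but without
    filtering the rest of the image.
    """
    L = min(int(math.ceil(4.0 * sigma)), pad)
    ax = np.arange(-L, L + 1, dtype=float)
    yy, xx = ax[:, None], ax[None, :]
    q = (yy**2 + xx**2) / (2.0 * sigma**2)
    g = np.exp(-q) / (2.0 * np.pi * sigma**2)
    kernel = -(sigma**2) * ((2.0 * q - 2.0) / sigma**2) * g
    patch = padded[r + pad - L : r + pad + L + 1, c + pad - L : c + pad + L + 1]
    return float(np.sum(kernel * patch))


def _refine_sigma(
    crop: np.ndarray, r: int, c: int, lo: float, hi: float
) -> tuple[float, float]:
    """Continuously maximize the scale-normalized LoG response at (r, c).

    blob_log quantizes sigma to its scale ladder; a bounded 1-D search
    over sigma removes that quantization, which would otherwise dominate
    the radius error for small colonies.
    """
    pad = int(math.ceil(4.0 * hi)) + 1
    padded = np.pad(crop, pad, mode="reflect")

    res = minimize_scalar(
        lambda s: -_log_point_response(padded, r, c, s, pad),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-3},
    )
    return float(res.x), float(-res.fun)


def radius_series(
    stack: Timelapse,
    roi: SquareROI,
    min_sigma: float = 1.0,
    max_sigma: float | None = None,
    n_scales: int = 8,
    threshold: float = 4.0,
    sigma_smooth: float = 1.0,
) -> GrowthTrace:
    """Estimate the colony radius in every frame of an ROI.

    Per frame the channel-summed crop is Gaussian-smoothed and blob-fit;
    the blob nearest the ROI center gives the scale, refined continuously
    and corrected for the smoothing kernel
    (sigma_colony^2 = sigma_detected^2 - sigma_smooth^2), and
    radius = sqrt(2) * sigma_colony. Frames with no acceptable detection
    (blank background, or nearest blob further than half the ROI
    half-width from the center) yield NaN.
    """
    H, W = stack.image_shape
    if not (0 <= roi.row_range[0] < roi.row_range[1] <= H
            and 0 <= roi.col_range[0] < roi.col_range[1] <= W):
        raise ValueError("ROI extends outside the image")
    if max_sigma is None:
        max_sigma = max(roi.half_width / SIGMA_TO_RADIUS, min_sigma * 2)

    center = (
        roi.center_rc[0] - roi.row_range[0],
        roi.center_rc[1] - roi.col_range[0],
    )
    radii = np.full(stack.n_frames, np.nan)
    for t in range(stack.n_frames):
        crop = roi.crop(stack.frames[t]).sum(axis=-1)
        smooth = ndi.gaussian_filter(crop, sigma_smooth) if sigma_smooth > 0 else crop
        if np.ptp(smooth) == 0:
            continue
        blobs = blob_log(
            smooth,
            min_sigma=min_sigma,
            max_sigma=max_sigma,
            num_sigma=n_scales,
            threshold=threshold,
            log_scale=True,
        )
        if blobs.size == 0:
            continue
        d2 = (blobs[:, 0] - center[0]) ** 2 + (blobs[:, 1] - center[1]) ** 2
        best = blobs[np.argmin(d2)]
        if math.sqrt(d2.min()) > 0.5 * roi.half_width:
            continue
        r0, c0 = int(round(best[0])), int(round(best[1]))
        sigma_det, resp = _refine_sigma(
            smooth, r0, c0, min_sigma * 0.5, max_sigma * 1.5
        )
        if resp < threshold:
            continue
        sigma2 = sigma_det**2 - sigma_smooth**2
        sigma_colony = math.sqrt(max(sigma2, 0.0625))
        radii[t] = SIGMA_TO_RADIUS * sigma_colony
    return GrowthTrace(colony_id=roi.colony_id, times=stack.times, radius_px=radii)


def fit_growth_model(trace: GrowthTrace) -> GrowthModelFit:
    """Nonlinear least-squares fit of the logistic area model.

    Initialization: Amax0 = max observed area; t0_0 = earliest time the
    area reaches Amax0 / 2; mu0 = 4 (dA/dt at t0_0) / Amax0, the logistic
    midpoint slope identity (dA/dt at t0 equals mu_max Amax / 4).
    """
    ok = np.isfinite(trace.area_px2)
    if ok.sum() < 4:
        raise ValueError(
            f"insufficient points: growth fit needs >= 4 defined areas, got {int(ok.sum())}"
        )
    t = trace.times[ok]
    a = trace.area_px2[ok]

    amax0 = float(a.max())
    if amax0 <= 0:
        raise ValueError("all observed areas are zero; nothing to fit")
    above = np.nonzero(a >= amax0 / 2)[0]
    i_mid = int(above[0])
    t0_0 = float(t[i_mid])
    if 0 < i_mid < len(t) - 1:
        dadt = (a[i_mid + 1] - a[i_mid - 1]) / (t[i_mid + 1] - t[i_mid - 1])
    elif i_mid == 0:
        dadt = (a[1] - a[0]) / (t[1] - t[0])
    else:
        dadt = (a[-1] - a[-2]) / (t[-1] - t[-2])
    mu0 = 4.0 * dadt / amax0
    if not np.isfinite(mu0) or mu0 <= 0:
        mu0 = 1.0 / max(t[-1] - t[0], 1.0)

    def residuals(p):
        return logistic_area(t, p[0], p[1], p[2]) - a

    res = least_squares(
        residuals,
        x0=[amax0, mu0, t0_0],
        bounds=([1e-12, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
        ftol=1e-12, xtol=1e-12, gtol=1e-12,
    )
    if not res.success:
        raise RuntimeError(
            f"growth model fit did not converge for colony {trace.colony_id}: "
            f"{res.message} (status {res.status})"
        )
    amax, mu_max, t0 = (float(v) for v in res.x)
    return GrowthModelFit(
        colony_id=trace.colony_id,
        Amax=amax,
        mu_max=mu_max,
        t0=t0,
        residual_rms=float(np.sqrt(np.mean(res.fun**2))),
        n_points_used=int(ok.sum()),
    )


def growth_rate_curve(fit: GrowthModelFit, times: np.ndarray) -> np.ndarray:
    """Specific growth rate mu(t) = mu_max / (exp(mu_max (t - t0)) + 1)."""
    t = np.asarray(times, dtype=float)
    return fit.mu_max * expit(-fit.mu_max * (t - fit.t0))


def kymograph(stack: Timelapse, roi: SquareROI) -> Kymograph:
    """Channel-summed intensity along the ROI's central image row, per frame."""
    row = int(round(roi.center_rc[0]))
    row = min(max(row, roi.row_range[0]), roi.row_range[1] - 1)
    values = stack.frames[:, row, roi.col_range[0] : roi.col_range[1], :].sum(axis=-1)
    return Kymograph(colony_id=roi.colony_id, values=values, times=stack.times)
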