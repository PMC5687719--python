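"""Fluorescent-protein expression-rate estimation.

Let F = I/A be the colony's mean fluorescence intensity per unit area
(channel-summed intensity inside the colony mask divided by the mask's
pixel count), a proxy for per-cell fluorophore concentration. As the
colony grows, newly made protein is diluted at the specific growth rate
mu(t), so the production (expression) rate is

    KF(t) = dF/dt + mu(t) F(t)        [intensity px^-1 h^-1]

F(t) is smoothed with a cubic smoothing spline whose analytic derivative
supplies dF/dt; mu(t) comes from the fitted logistic growth model's
closed form, never from numerically differentiating the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import UnivariateSpline

from colonylapse.detect import SquareROI
from colonylapse.growth import GrowthModelFit, growth_rate_curve
from colonylapse.stack import Timelapse

__all__ = [
    "IntensityTrace",
    "SmoothedTrace",
    "ExpressionRateCurve",
    "circle_mask",
    "intensity_series",
    "smooth_trace",
    "expression_rate",
]


@dataclass(frozen=True)
class IntensityTrace:
    """Per-frame channel-summed intensity inside the colony mask.

    ``mean_F = total_I / n_pixels`` is the I/A of the expression-rate
    formula; frames with an empty mask hold NaN.
    """

    colony_id: int
    times: np.ndarray
    total_I: np.ndarray
    n_pixels: np.ndarray
    mean_F: np.ndarray

    def __post_init__(self) -> None:
        for name in ("times", "total_I", "n_pixels", "mean_F"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (len(self.times) == len(self.total_I) == len(self.n_pixels) == len(self.mean_F)):
            raise ValueError("all trace arrays must share one length")


@dataclass(frozen=True)
class SmoothedTrace:
    """Cubic smoothing spline over (time, mean_F) with analytic derivative.

    Evaluation outside the fitted time range raises rather than
    extrapolates: a cubic polynomial tail has no biological meaning.
    """

    colony_id: int
    spline: UnivariateSpline
    t_range: tuple[float, float]
    smoothing_factor: float

    def _check(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if np.any(t < self.t_range[0]) or np.any(t > self.t_range[1]):
            raise ValueError(
                f"time outside the smoothed range [{self.t_range[0]}, {self.t_range[1]}]"
            )
        return t

    def __call__(self, t):
        return self.spline(self._check(t))

    def derivative(self, t):
        return self.spline.derivative()(self._check(t))


@dataclass(frozen=True)
class ExpressionRateCurve:
    """KF(t) per colony, in intensity px^-1 h^-1."""

    colony_id: int
    times: np.ndarray
    KF: np.ndarray


def circle_mask(
    shape: tuple[int, int],
    center_rc: tuple[float, float],
    radius: float,
) -> np.ndarray:
    """Boolean mask of pixels whose centers lie within *radius* of the center."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    d2 = (rr - center_rc[0]) ** 2 + (cc - center_rc[1]) ** 2
    return d2 <= radius**2


def intensity_series(
    stack: Timelapse,
    roi: SquareROI,
    fit: GrowthModelFit,
    blob_center: tuple[float, float] | None = None,
) -> IntensityTrace:
    """Channel-summed intensity inside the fitted-radius colony mask.

    The mask at frame t is the circle of radius r(t) = sqrt(A_fit(t)/pi)
    centered on the blob center, intersected with the ROI. The fitted
    radius curve is used rather than the noisy per-frame radius so that
    early, poorly detected frames still get a sensible mask.
    """
    if blob_center is None:
        blob_center = roi.center_rc
    center_local = (
        blob_center[0] - roi.row_range[0],
        blob_center[1] - roi.col_range[0],
    )
    crops = roi.crop(stack.frames.transpose(1, 2, 3, 0)).transpose(3, 0, 1, 2)
    chansum = crops.sum(axis=-1)  # T x Hroi x Wroi

    T = stack.n_frames
    total = np.zeros(T)
    npix = np.zeros(T)
    radii = np.atleast_1d(fit.radius(stack.times))
    for t in range(T):
        mask = circle_mask(chansum.shape[1:], center_local, radii[t])
        npix[t] = mask.sum()
        total[t] = chansum[t][mask].sum()
    if npix.max() == 0:
        raise ValueError(
            f"colony {roi.colony_id}: mask is empty at every frame (ROI/fit mismatch?)"
        )
    mean = np.divide(total, npix, out=np.full(T, np.nan), where=npix > 0)
    return IntensityTrace(
        colony_id=roi.colony_id,
        times=stack.times,
        total_I=total,
        n_pixels=npix,
        mean_F=mean,
    )


def default_smoothing_factor(times: np.ndarray, values: np.ndarray) -> float:
    """n * noise_scale^2 with noise_scale the median absolute successive
    difference of the values — a crude but parameter-free noise estimate."""
    noise = float(np.median(np.abs(np.diff(values))))
    return len(values) * noise**2


def smooth_trace(
    trace: IntensityTrace,
    smoothing_factor: float | None = None,
) -> SmoothedTrace:
    """Cubic smoothing spline on (time, mean_F).

    *smoothing_factor* is the target sum of squared residuals handed to
    the spline; 0 interpolates exactly, None picks the default based on
    the trace's own successive-difference noise estimate.
    """
    ok = np.isfinite(trace.mean_F)
    if ok.sum() < 4:
        raise ValueError("smoothing needs at least 4 defined points")
    t = trace.times[ok]
    f = trace.mean_F[ok]
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if smoothing_factor is None:
        smoothing_factor = default_smoothing_factor(t, f)
    spline = UnivariateSpline(t, f, k=3, s=smoothing_factor)
    return SmoothedTrace(
        colony_id=trace.colony_id,
        spline=spline,
        t_range=(float(t[0]), float(t[-1])),
        smoothing_factor=float(smoothing_factor),
    )


def expression_rate(
    smoothed: SmoothedTrace,
    fit: GrowthModelFit,
    times: np.ndarray,
) -> ExpressionRateCurve:
    """KF(t) = F'(t) + mu(t) F(t), the dilution-corrected expression rate."""
    t = np.asarray(times, dtype=float)
    F = np.asarray(smoothed(t), dtype=float)
    dF = np.asarray(smoothed.derivative(t), dtype=float)
    mu = growth_rate_curve(fit, t)
    return ExpressionRateCurve(colony_id=smoothed.colony_id, times=t, KF=dF + mu * F)
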