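"""Fit logistic growth curves to each colony.

For every detected colony, estimates the radius in each frame by blob-
fitting its ROI, fits the logistic area model
A(t) = Amax / (1 + exp(-mu_max (t - t0))), and prints the fitted
parameters next to the simulator's ground truth.
"""

from pathlib import Path

import numpy as np

from colonylapse import (
    detect_colonies,
    fit_growth_model,
    growth_rate_curve,
    load_timelapse,
    make_rois,
    radius_series,
    smooth_projection,
    subtract_background,
    temporal_sum_projection,
)
from colonylapse.simulate import grid_plate_spec, write_plate

plate = Path("scratch/example_plate")
if not plate.exists():
    write_plate(grid_plate_spec(2, 3, seed=7), plate)
truth = __import__("pandas").read_csv(plate / "ground_truth.csv")

stack = subtract_background(load_timelapse(plate, "img_*.png", frame_interval_h=0.5))
projection = smooth_projection(temporal_sum_projection(stack), 2.0)
blobs = detect_colonies(projection)
rois = make_rois(blobs, 3.0, stack.image_shape)

print("colony  Amax_fit  Amax_true  mu_fit  mu_true  t0_fit  t0_true")
for blob, roi in zip(blobs, rois):
    trace = radius_series(stack, roi)
    fit = fit_growth_model(trace)
    i = int(np.argmin((truth.row - blob.center_rc[0]) ** 2
                      + (truth.col - blob.center_rc[1]) ** 2))
    gt = truth.iloc[i]
    print(
        f"  {blob.id}    {fit.Amax:8.0f}  {gt.Amax:8.0f}  {fit.mu_max:.3f}   "
        f"{gt.mu_max:.3f}   {fit.t0:5.2f}   {gt.t0:5.2f}"
    )

fit0 = fit_growth_model(radius_series(stack, rois[0]))
mu_now = growth_rate_curve(fit0, np.array([fit0.t0]))[0]
print(f"\ncolony 0 growth rate at its half-maximum time: {mu_now:.3f} /h")
print("(exactly mu_max / 2 there; the rate decays to 0 as the colony plateaus)")
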