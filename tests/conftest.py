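"""Shared fixtures: small synthetic plates with known ground truth."""

import numpy as np
import pytest

from colonylapse import subtract_background
from colonylapse.detect import SquareROI
from colonylapse.simulate import ColonySpec, PlateSpec, render_plate


@pytest.fixture(scope="session")
def single_colony_spec() -> PlateSpec:
    """One colony, default noise, 24 h at 0.5 h — the workhorse fixture."""
    return PlateSpec(
        image_shape=(120, 120),
        n_frames=49,
        frame_interval_h=0.5,
        seed=3,
        colonies=[
            ColonySpec(
                center_rc=(60.0, 60.0),
                Amax=2000.0,
                mu_max=0.5,
                t0=12.0,
                KF_true=25.0,
                emission=(0.25, 0.60, 0.15),
                label="demo",
            )
        ],
        noise_sigma=2.0,
    )


@pytest.fixture(scope="session")
def single_colony_plate(single_colony_spec):
    """(background-corrected stack, ground-truth table, ColonySpec)."""
    lapse, truth = render_plate(single_colony_spec, quantize=True)
    return subtract_background(lapse), truth, single_colony_spec.colonies[0]


@pytest.fixture(scope="session")
def single_colony_roi() -> SquareROI:
    """ROI covering the single-colony fixture's colony."""
    return SquareROI(
        colony_id=0,
        center_rc=(60.0, 60.0),
        half_width=40,
        row_range=(20, 101),
        col_range=(20, 101),
    )


@pytest.fixture()
def uniform_stack():
    """3-frame stack with every pixel at (10, 10, 10)."""
    from colonylapse import Timelapse

    frames = np.full((3, 16, 16, 3), 10.0)
    return Timelapse(frames=frames, times=np.array([0.0, 0.5, 1.0]))
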