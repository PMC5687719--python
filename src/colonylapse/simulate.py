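"""Synthetic fluorescent-colony plate simulator.

The generative twin of the analysis pipeline, used as its test bed:

* Colony area follows the logistic model A(t) = Amax / (1 + e^(-mu_max (t - t0))).
* Per-pixel fluorescence F(t) (intensity per pixel inside the colony)
  obeys dF/dt = KF - mu(t) F — constant production at rate KF, dilution
  at the specific growth rate mu(t) — integrated numerically.
* Each protein's emission splits F across the R, G, B channels with a
  fixed emission vector normalized to channel-sum 1, so the
  channel-summed pixel value equals F directly.
* Frames are discs with area-coverage antialiased edges on a uniform
  background, plus additive Gaussian camera noise, clipped to the bit
  depth's range.

The model omits lens PSF, filter spectra, spatial illumination
nonuniformity, Poisson photon statistics and non-disc morphology.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from colonylapse.growth import logistic_area
from colonylapse.stack import Timelapse

__all__ = [
    "ColonySpec",
    "PlateSpec",
    "solve_fluorescence",
    "render_plate",
    "write_plate",
    "grid_plate_spec",
]


@dataclass(frozen=True)
class ColonySpec:
    """Ground-truth parameters of one simulated colony."""

    center_rc: tuple[float, float]
    Amax: float  # plateau area, px^2
    mu_max: float  # maximal specific growth rate, h^-1
    t0: float  # half-maximum time, h
    KF_true: float  # expression rate, intensity px^-1 h^-1
    F0: float = 0.0  # initial fluorescence, intensity px^-1
    emission: tuple[float, float, float] = (0.0, 1.0, 0.0)
    label: str = "strain"

    def __post_init__(self) -> None:
        if self.Amax <= 0 or self.mu_max <= 0:
            raise ValueError("Amax and mu_max must be positive")
        e = np.asarray(self.emission, dtype=float)
        if np.any(e < 0) or not math.isclose(float(e.sum()), 1.0, rel_tol=1e-9):
            raise ValueError(
                f"emission must be non-negative and sum to 1, got {tuple(e)}"
            )

    def radius(self, t) -> np.ndarray:
        return np.sqrt(logistic_area(t, self.Amax, self.mu_max, self.t0) / np.pi)

    def mu(self, t):
        from scipy.special import expit

        return self.mu_max * expit(-self.mu_max * (np.asarray(t, float) - self.t0))


@dataclass(frozen=True)
class PlateSpec:
    """Full description of a synthetic plate timelapse; seed is mandatory."""

    image_shape: tuple[int, int]
    n_frames: int
    frame_interval_h: float
    seed: int
    colonies: list[ColonySpec] = field(default_factory=list)
    background: tuple[float, float, float] = (12.0, 9.0, 6.0)
    noise_sigma: float = 2.0
    bit_depth: int = 8
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        if self.n_frames < 1 or self.frame_interval_h <= 0:
            raise ValueError("need n_frames >= 1 and positive frame interval")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        H, W = self.image_shape
        for i, col in enumerate(self.colonies):
            r, c = col.center_rc
            if not (0 <= r < H and 0 <= c < W):
                raise ValueError(
                    f"colony {i} ({col.label!r}) center {col.center_rc} is outside "
                    f"the {H}x{W} image"
                )

    @property
    def times(self) -> np.ndarray:
        return self.frame_interval_h * np.arange(self.n_frames, dtype=float)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "PlateSpec":
        with open(path) as fh:
            raw = json.load(fh)
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown PlateSpec keys: {sorted(unknown)}")
        colonies = [
            ColonySpec(**{**c, "center_rc": tuple(c["center_rc"]),
                          "emission": tuple(c["emission"])})
            for c in raw.pop("colonies", [])
        ]
        for key in ("image_shape", "background"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(colonies=colonies, **raw)


def solve_fluorescence(
    spec: ColonySpec,
    times: np.ndarray,
    max_step_h: float = 0.01,
) -> np.ndarray:
    """Integrate dF/dt = KF - mu(t) F from F(times[0]) = F0.

    Classical fixed-step 4th-order Runge-Kutta with step <= *max_step_h*;
    returns F at exactly the requested times.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or (len(times) > 1 and np.any(np.diff(times) <= 0)):
        raise ValueError("times must be 1-D and strictly increasing")

    def rhs(t: float, F: float) -> float:
        return spec.KF_true - float(spec.mu(t)) * F

    out = np.empty_like(times)
    out[0] = F = float(spec.F0)
    for i in range(1, len(times)):
        t, t_end = times[i - 1], times[i]
        n_sub = max(1, math.ceil((t_end - t) / max_step_h))
        h = (t_end - t) / n_sub
        for _ in range(n_sub):
            k1 = rhs(t, F)
            k2 = rhs(t + h / 2, F + h / 2 * k1)
            k3 = rhs(t + h / 2, F + h / 2 * k2)
            k4 = rhs(t + h, F + h * k3)
            F += h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
        out[i] = F
    return out


def _check_overlaps(spec: PlateSpec) -> None:
    """Colony discs must stay disjoint at every frame; radii are monotone
    increasing, so checking the final frame suffices."""
    t_end = spec.times[-1]
    cols = spec.colonies
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            ri = float(cols[i].radius(t_end))
            rj = float(cols[j].radius(t_end))
            d = math.dist(cols[i].center_rc, cols[j].center_rc)
            if d < ri + rj:
                raise ValueError(
                    f"colonies {i} and {j} overlap (centers {d:.1f} px apart, "
                    f"radii {ri:.1f} + {rj:.1f}); set allow_overlap to sum them"
                )


def _disc_coverage(
    shape: tuple[int, int], center: tuple[float, float], radius: float
) -> np.ndarray:
    """Per-pixel area coverage of a disc, linear-ramp edge approximation."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    dist = np.sqrt((rr - center[0]) ** 2 + (cc - center[1]) ** 2)
    return np.clip(radius + 0.5 - dist, 0.0, 1.0)


def render_plate(
    spec: PlateSpec,
    quantize: bool = False,
) -> tuple[Timelapse, pd.DataFrame]:
    """Render the plate timelapse and its ground-truth table.

    With ``quantize`` the frames are rounded to integer digital levels,
    exactly what :func:`write_plate` stores on disk; without it pixel
    values are continuous, which keeps noise-free closed-form checks
    exact.
    """
    if not spec.allow_overlap:
        _check_overlaps(spec)
    H, W = spec.image_shape
    times = spec.times
    rng = np.random.default_rng(spec.seed)
    maxval = float(2**spec.bit_depth - 1)

    fluor = [solve_fluorescence(col, times) for col in spec.colonies]
    frames = np.empty((spec.n_frames, H, W, 3), dtype=float)
    for t_idx, t in enumerate(times):
        frame = np.tile(np.asarray(spec.background, float), (H, W, 1))
        for col, F in zip(spec.colonies, fluor):
            r = float(col.radius(t))
            r0 = max(0, int(math.floor(col.center_rc[0] - r - 1)))
            r1 = min(H, int(math.ceil(col.center_rc[0] + r + 2)))
            c0 = max(0, int(math.floor(col.center_rc[1] - r - 1)))
            c1 = min(W, int(math.ceil(col.center_rc[1] + r + 2)))
            if r0 >= r1 or c0 >= c1:
                continue
            cov = _disc_coverage(
                (r1 - r0, c1 - c0),
                (col.center_rc[0] - r0, col.center_rc[1] - c0),
                r,
            )
            patch = cov[..., None] * (F[t_idx] * np.asarray(col.emission, float))
            frame[r0:r1, c0:c1, :] += patch
        if spec.noise_sigma > 0:
            frame = frame + rng.normal(0.0, spec.noise_sigma, frame.shape)
        frames[t_idx] = np.clip(frame, 0.0, maxval)
    if quantize:
        frames = np.round(frames)

    truth = pd.DataFrame(
        {
            "colony_id": range(len(spec.colonies)),
            "label": [c.label for c in spec.colonies],
            "row": [c.center_rc[0] for c in spec.colonies],
            "col": [c.center_rc[1] for c in spec.colonies],
            "Amax": [c.Amax for c in spec.colonies],
            "mu_max": [c.mu_max for c in spec.colonies],
            "t0": [c.t0 for c in spec.colonies],
            "KF": [c.KF_true for c in spec.colonies],
            "F0": [c.F0 for c in spec.colonies],
            "eR": [c.emission[0] for c in spec.colonies],
            "eG": [c.emission[1] for c in spec.colonies],
            "eB": [c.emission[2] for c in spec.colonies],
        }
    )
    stack = Timelapse(frames=frames, times=times, bit_depth=spec.bit_depth)
    return stack, truth


def write_plate(spec: PlateSpec, out_dir: str | Path) -> Path:
    """Render and write the plate: frames (PNG for 8-bit, TIFF for
    16-bit), ground_truth.csv, and the spec as platespec.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stack, truth = render_plate(spec, quantize=True)
    ext = "png" if spec.bit_depth == 8 else "tif"
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    for i, frame in enumerate(stack.frames):
        path = out_dir / f"img_{i:05d}.{ext}"
        arr = frame.astype(dtype)
        if spec.bit_depth == 8:
            iio.imwrite(path, arr)
        else:
            tifffile.imwrite(path, arr)
    truth.to_csv(out_dir / "ground_truth.csv", index=False)
    spec.to_json(out_dir / "platespec.json")
    return out_dir


def grid_plate_spec(
    n_rows: int,
    n_cols: int,
    spacing_px: float = 90.0,
    margin_px: float = 60.0,
    n_frames: int = 49,
    frame_interval_h: float = 0.5,
    seed: int = 0,
    mu_max: float = 0.5,
    Amax_range: tuple[float, float] = (1500.0, 3000.0),
    t0_range: tuple[float, float] = (10.0, 14.0),
    KF_true: float = 25.0,
    emission: tuple[float, float, float] = (0.25, 0.60, 0.15),
    labels: list[str] | None = None,
    noise_sigma: float = 2.0,
    background: tuple[float, float, float] = (12.0, 9.0, 6.0),
) -> PlateSpec:
    """Plate of colonies on a regular grid with randomized parameters.

    Amax and t0 are drawn uniformly from their ranges with the plate's
    own seeded generator; centers are jittered by up to 3 px. *labels*
    may give a per-colony (strain, emission) assignment as strings; with
    None all colonies share *emission*.
    """
    rng = np.random.default_rng(seed)
    H = int(2 * margin_px + (n_rows - 1) * spacing_px)
    W = int(2 * margin_px + (n_cols - 1) * spacing_px)
    colonies = []
    for i in range(n_rows):
        for j in range(n_cols):
            k = i * n_cols + j
            center = (
                margin_px + i * spacing_px + rng.uniform(-3, 3),
                margin_px + j * spacing_px + rng.uniform(-3, 3),
            )
            colonies.append(
                ColonySpec(
                    center_rc=(float(center[0]), float(center[1])),
                    Amax=float(rng.uniform(*Amax_range)),
                    mu_max=mu_max,
                    t0=float(rng.uniform(*t0_range)),
                    KF_true=KF_true,
                    F0=0.0,
                    emission=emission,
                    label=labels[k] if labels else "strain",
                )
            )
    return PlateSpec(
        image_shape=(H, W),
        n_frames=n_frames,
        frame_interval_h=frame_interval_h,
        seed=seed,
        colonies=colonies,
        background=background,
        noise_sigma=noise_sigma,
    )
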