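"""Strain classification from RGB channel signatures.

Each fluorescent protein's emission spectrum overlaps the camera's R, G
and B channel sensitivities in a fixed proportion, so colonies of one
strain fall along a characteristic line through the origin in the
(R_total, G_total) plane. A line is fit per protein from single-strain
plates (through-origin least squares), and unknown colonies are assigned
to the angularly closest line — brightness cancels, only the channel
ratio matters.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from colonylapse.detect import SquareROI
from colonylapse.expression import circle_mask
from colonylapse.growth import GrowthModelFit
from colonylapse.stack import Timelapse

__all__ = [
    "ChannelTotals",
    "ProteinSignature",
    "ClassificationResult",
    "channel_totals",
    "fit_signature",
    "classify_colonies",
    "save_signatures",
    "load_signatures",
]


@dataclass(frozen=True)
class ChannelTotals:
    """Background-subtracted per-channel sums over the colony mask."""

    colony_id: int
    R_total: float
    G_total: float
    B_total: float

    def __post_init__(self) -> None:
        if min(self.R_total, self.G_total, self.B_total) < 0:
            raise ValueError("channel totals must be non-negative")


@dataclass(frozen=True)
class ProteinSignature:
    """A protein's characteristic (R, G) line: G = slope * R through the origin."""

    label: str
    slope: float
    angle: float  # atan(slope), radians
    n_colonies: int

    def __post_init__(self) -> None:
        if self.n_colonies < 2:
            raise ValueError("a signature needs at least 2 colonies")
        if self.slope < 0:
            raise ValueError("slope must be non-negative")


@dataclass(frozen=True)
class ClassificationResult:
    """Assignment of one colony to the angularly closest signature line.

    ``assigned_label`` is None for unclassifiable colonies (zero signal
    in both channels); ``runner_up_margin`` is 0 on a documented tie.
    """

    colony_id: int
    assigned_label: str | None
    angular_distance: float
    runner_up_margin: float


def channel_totals(
    stack: Timelapse,
    roi: SquareROI,
    fit: GrowthModelFit,
    blob_center: tuple[float, float] | None = None,
    reference: str = "endpoint",
) -> ChannelTotals:
    """Per-channel sums over the fitted-endpoint-radius colony mask.

    ``endpoint`` (default) sums the last frame only — the colony at its
    final size; ``time_sum`` sums over all frames with the same endpoint
    mask.
    """
    if reference not in ("endpoint", "time_sum"):
        raise ValueError(f"reference must be 'endpoint' or 'time_sum', got {reference!r}")
    if blob_center is None:
        blob_center = roi.center_rc
    center_local = (
        blob_center[0] - roi.row_range[0],
        blob_center[1] - roi.col_range[0],
    )
    radius = float(fit.radius(stack.times[-1]))
    mask = circle_mask(roi.shape, center_local, radius)
    if not mask.any():
        raise ValueError(f"colony {roi.colony_id}: empty endpoint mask")
    if reference == "endpoint":
        crop = roi.crop(stack.frames[-1])  # Hroi x Wroi x 3
        sums = crop[mask].sum(axis=0)
    else:
        crops = stack.frames[:, roi.row_range[0]:roi.row_range[1],
                             roi.col_range[0]:roi.col_range[1], :]
        sums = crops[:, mask, :].sum(axis=(0, 1))
    return ChannelTotals(
        colony_id=roi.colony_id,
        R_total=float(sums[0]),
        G_total=float(sums[1]),
        B_total=float(sums[2]),
    )


def fit_signature(totals: list[ChannelTotals], label: str) -> ProteinSignature:
    """Through-origin least squares of G on R: slope = sum(R G) / sum(R^2).

    After background subtraction zero protein implies zero signal in both
    channels, so the line is constrained through the origin.
    """
    usable = [t for t in totals if t.R_total + t.G_total > 0]
    if len(usable) < 2:
        raise ValueError(
            f"insufficient colonies for signature {label!r}: "
            f"need >= 2 with nonzero signal, got {len(usable)}"
        )
    R = np.array([t.R_total for t in usable])
    G = np.array([t.G_total for t in usable])
    denom = float(np.sum(R**2))
    if denom == 0:
        # all signal in G: a vertical line, slope -> +inf; report pi/2 angle
        return ProteinSignature(label=label, slope=math.inf,
                                angle=math.pi / 2, n_colonies=len(usable))
    slope = float(np.sum(R * G)) / denom
    return ProteinSignature(
        label=label, slope=slope, angle=math.atan(slope), n_colonies=len(usable)
    )


def classify_colonies(
    totals: list[ChannelTotals],
    signatures: list[ProteinSignature],
) -> list[ClassificationResult]:
    """Assign each colony to the signature whose line is angularly closest.

    The colony's own angle is atan2(G_total, R_total); distance is the
    absolute angle difference. Ties go to the lexicographically first
    label and are flagged with runner_up_margin = 0. Colonies with zero
    signal in both channels are unclassifiable (label None).
    """
    if not signatures:
        raise ValueError("at least one signature is required")
    labels = [s.label for s in signatures]
    if len(set(labels)) != len(labels):
        raise ValueError(f"signature labels must be distinct, got {labels}")
    sigs = sorted(signatures, key=lambda s: s.label)

    results = []
    for tot in totals:
        if tot.R_total == 0 and tot.G_total == 0:
            results.append(ClassificationResult(tot.colony_id, None, math.nan, math.nan))
            continue
        angle = math.atan2(tot.G_total, tot.R_total)
        dists = np.array([abs(angle - s.angle) for s in sigs])
        order = np.argsort(dists, kind="stable")  # stable -> lexicographic tiebreak
        best = int(order[0])
        margin = float(dists[order[1]] - dists[best]) if len(sigs) > 1 else math.inf
        results.append(
            ClassificationResult(
                colony_id=tot.colony_id,
                assigned_label=sigs[best].label,
                angular_distance=float(dists[best]),
                runner_up_margin=margin,
            )
        )
    return results


def save_signatures(signatures: list[ProteinSignature], path: str | Path) -> None:
    """Write signatures as CSV: label,slope,angle_rad,n_colonies."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "slope", "angle_rad", "n_colonies"])
        for s in signatures:
            w.writerow([s.label, repr(s.slope), repr(s.angle), s.n_colonies])


def load_signatures(path: str | Path) -> list[ProteinSignature]:
    """Re-load signatures written by :func:`save_signatures`."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                ProteinSignature(
                    label=row["label"],
                    slope=float(row["slope"]),
                    angle=float(row["angle_rad"]),
                    n_colonies=int(row["n_colonies"]),
                )
            )
    return out
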