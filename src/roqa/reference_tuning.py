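"""Reference-based adaptive threshold tuning.

The white top-hat threshold controls how far each segmented particle extends
into the blurred intensity falloff around a nucleus, so it directly sets the
apparent particle size. To pick it objectively, a few superficial nuclei are
measured in a higher-resolution reference image (seen longest and shortest
axis of the silhouette from the reference objective's viewing direction),
and the threshold is chosen so the matching voxel particles — viewed from
the same aspect — reproduce those axes best. Here the manual by-eye match is
automated as a grid search minimizing the mean relative axis error; a grid
of size 1 recovers manual mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import ConvexHull

from .segmentation import (
    LabelVolume,
    border_kill,
    fill_holes,
    label_particles,
    threshold_band,
)
from .volume_io import IntensityVolume

__all__ = [
    "ReferenceMeasurement",
    "projected_axes",
    "tune_threshold",
    "read_reference_csv",
]

_AXIS_INDEX = {"z": 0, "y": 1, "x": 2}


@dataclass
class ReferenceMeasurement:
    """One optically measured reference nucleus.

    Location is the approximate particle position in µm (volume frame,
    z/y/x); the axes are the longest and shortest caliper diameters of the
    nucleus silhouette as seen along `view_axis`.
    """

    location_um: tuple[float, float, float]
    seen_longest_um: float
    seen_shortest_um: float
    view_axis: str = "z"

    def __post_init__(self) -> None:
        if not (self.seen_longest_um >= self.seen_shortest_um > 0):
            raise ValueError("need longest >= shortest > 0")
        if self.view_axis not in _AXIS_INDEX:
            raise ValueError("view_axis must be one of 'z', 'y', 'x'")


def projected_axes(
    mask: np.ndarray,
    view_axis: str,
    spacing: tuple[float, float, float],
) -> tuple[float, float]:
    """Longest and shortest caliper (Feret) diameters in µm of a particle's
    silhouette projected along `view_axis`.

    The silhouette is the 2D shadow of the voxel mask; pixel corner points
    feed a convex hull, the max Feret is the hull diameter and the min Feret
    comes from rotating calipers over the hull edges.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty particle")
    ax = _AXIS_INDEX[view_axis]
    shadow = mask.any(axis=ax)
    keep = [i for i in range(3) if i != ax]
    sp = (spacing[keep[0]], spacing[keep[1]])
    ij = np.argwhere(shadow).astype(float)
    # pixel corners so single-pixel rows still have finite width
    corners = np.concatenate(
        [ij + d for d in ((0, 0), (0, 1), (1, 0), (1, 1))]
    ) * np.asarray(sp)
    corners = np.unique(corners, axis=0)
    if len(corners) < 3:
        raise ValueError("silhouette degenerate")
    hull = ConvexHull(corners)
    pts = corners[hull.vertices]
    dists = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    longest = float(dists.max())
    shortest = _min_feret(pts)
    return longest, shortest


def _min_feret(hull_pts: np.ndarray) -> float:
    """Minimum caliper width of a convex polygon (rotating calipers)."""
    n = len(hull_pts)
    best = math.inf
    for i in range(n):
        p0, p1 = hull_pts[i], hull_pts[(i + 1) % n]
        edge = p1 - p0
        norm = np.linalg.norm(edge)
        if norm == 0:
            continue
        normal = np.array([-edge[1], edge[0]]) / norm
        width = np.ptp((hull_pts - p0) @ normal)
        best = min(best, float(width))
    return best


def _segment_at(wth: IntensityVolume, threshold: float, upper: float) -> LabelVolume:
    mask = threshold_band(wth, threshold, upper)
    mask = fill_holes(mask)
    return border_kill(label_particles(mask))


def tune_threshold(
    wth: IntensityVolume,
    refs: list[ReferenceMeasurement],
    candidates,
    upper: float = float("inf"),
    match_radius_um: float = 20.0,
) -> tuple[float, pd.DataFrame]:
    """Grid-search the WTH threshold against reference axis measurements.

    For each candidate threshold the top-hat volume is segmented, the
    particle whose centroid lies nearest each reference location (within
    `match_radius_um`) is projected along the reference view axis, and the
    mean relative error of (longest, shortest) axes against the optical
    measurement is the loss. Returns ``(best_threshold, table)`` where the
    table lists per-candidate loss and match counts. Ties break toward the
    higher threshold. References never matched at any candidate are reported
    unmatched; if no reference ever matches, tuning fails.
    """
    candidates = sorted(float(c) for c in candidates)
    if not candidates:
        raise ValueError("candidate grid is empty")
    if not refs:
        raise ValueError("need at least one reference measurement")
    spacing = np.asarray(wth.spacing)
    rows = []
    ever_matched = [False] * len(refs)
    for thr in candidates:
        lv = _segment_at(wth, thr, upper)
        errors = []
        n_matched = 0
        if lv.n_particles:
            coms = ndimage.center_of_mass(
                lv.labels > 0, lv.labels, range(1, lv.n_particles + 1)
            )
            cents = (np.asarray(coms) + 0.5) * spacing
        for k, ref in enumerate(refs):
            if lv.n_particles == 0:
                continue
            d = np.linalg.norm(cents - np.asarray(ref.location_um), axis=1)
            j = int(np.argmin(d))
            if d[j] > match_radius_um:
                continue
            ever_matched[k] = True
            n_matched += 1
            sub = lv.labels == j + 1
            longest, shortest = projected_axes(sub, ref.view_axis, wth.spacing)
            errors.append(
                0.5
                * (
                    abs(longest - ref.seen_longest_um) / ref.seen_longest_um
                    + abs(shortest - ref.seen_shortest_um) / ref.seen_shortest_um
                )
            )
        loss = float(np.mean(errors)) if errors else math.inf
        rows.append({"threshold": thr, "loss": loss, "n_matched": n_matched})
    table = pd.DataFrame(rows)
    if not any(ever_matched):
        raise ValueError("no reference location matched a particle at any candidate threshold")
    finite = table[np.isfinite(table["loss"])]
    best_loss = finite["loss"].min()
    # ties (within float identity) break toward the higher threshold
    best = finite[finite["loss"] == best_loss]["threshold"].max()
    return float(best), table


def read_reference_csv(path) -> list[ReferenceMeasurement]:
    """Read reference measurements from CSV with columns
    z_um, y_um, x_um, seen_longest_um, seen_shortest_um, view_axis."""
    df = pd.read_csv(path)
    return [
        ReferenceMeasurement(
            (row["z_um"], row["y_um"], row["x_um"]),
            row["seen_longest_um"],
            row["seen_shortest_um"],
            str(row.get("view_axis", "z")),
        )
        for _, row in df.iterrows()
    ]
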