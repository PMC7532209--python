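"""Locally adaptive segmentation of bright round particles.

The core extraction step is the white top-hat (WTH) transform — the image
minus its grayscale opening — which isolates bright features smaller than the
structuring element regardless of the slowly varying background underneath.
The segmented mask is then cleaned with hole filling, border kill (particles
touching any field-of-view face are incomplete and removed), and a physical
volume sieve. Connectivity is 26 (full 3×3×3 neighborhood) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import ball
from skimage.restoration import denoise_nl_means

from .volume_io import IntensityVolume

__all__ = [
    "BinaryVolume",
    "LabelVolume",
    "SegmentationParams",
    "white_top_hat",
    "threshold_band",
    "fill_holes",
    "label_particles",
    "border_kill",
    "sieve_volume",
    "nlm_denoise",
    "ball_closing",
    "binary_smoothing",
    "segment_volume",
]

#: 26-connectivity structuring element (full 3×3×3 neighborhood).
STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class BinaryVolume:
    """Boolean foreground mask with the geometry of its source volume."""

    mask: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def voxel_volume(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx


@dataclass
class LabelVolume:
    """Integer particle labels; 0 is background, positive labels are
    26-connected components numbered consecutively from 1."""

    labels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3D")
        if self.labels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def n_particles(self) -> int:
        return int(self.labels.max(initial=0))

    @property
    def voxel_volume(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx

    def voxel_counts(self) -> dict[int, int]:
        """Voxel count per label, {label: count}, labels ascending."""
        ids, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts)}


@dataclass
class SegmentationParams:
    """Parameter bundle for the µCT/CLSM segmentation chain.

    ``wth_kernel`` is the structuring-element size in voxels (cube side, or
    ball diameter when ``wth_element='ball'``); ``wth_lower``/``wth_upper``
    bound the accepted top-hat intensities (both inclusive; the upper limit
    defaults to the dtype maximum so the densest label is always kept);
    the sieve limits are physical volumes in µm³.
    """

    wth_kernel: int = 10
    wth_lower: float = 2700.0
    wth_upper: float = float(2**16 - 1)
    min_volume_um3: float = 15.0
    max_volume_um3: float | None = None
    wth_element: str = "cube"
    crop_bottom_um: float = 0.0
    connectivity: int = field(default=26)

    def __post_init__(self) -> None:
        if self.wth_kernel < 1:
            raise ValueError("wth_kernel must be >= 1")
        if self.wth_lower > self.wth_upper:
            raise ValueError("wth_lower must be <= wth_upper")
        if self.min_volume_um3 < 0:
            raise ValueError("min_volume_um3 must be >= 0")
        if self.max_volume_um3 is not None and self.max_volume_um3 < self.min_volume_um3:
            raise ValueError("max_volume_um3 must be >= min_volume_um3")
        if self.connectivity != 26:
            raise ValueError("only 26-connectivity is supported")
        if self.wth_element not in ("cube", "ball"):
            raise ValueError("wth_element must be 'cube' or 'ball'")


def _wth_footprint(kernel: int, element: str) -> tuple:
    if element == "ball":
        # ball(r) has diameter 2r+1; interpret kernel as the diameter
        r = max(1, kernel // 2)
        return {"footprint": ball(r)}
    return {"size": (kernel, kernel, kernel)}


def white_top_hat(v: IntensityVolume, kernel: int, element: str = "cube") -> IntensityVolume:
    """White top-hat: the volume minus its grayscale opening.

    Extracts bright features smaller than the structuring element while
    suppressing larger-scale background. The result is non-negative because
    a grayscale opening never exceeds its input.
    """
    if kernel < 1:
        raise ValueError("kernel must be >= 1")
    if kernel > min(v.data.shape):
        raise ValueError(
            f"kernel {kernel} exceeds smallest volume dimension {min(v.data.shape)}"
        )
    opened = ndimage.grey_opening(v.data, **_wth_footprint(kernel, element))
    wth = v.data - opened  # unsigned-safe: opening <= original voxelwise
    return v.with_data(wth, f"white top-hat kernel={kernel} ({element})")


def threshold_band(wth: IntensityVolume, lower: float, upper: float) -> BinaryVolume:
    """Binary mask of voxels with ``lower <= value <= upper`` (both inclusive)."""
    if lower > upper:
        raise ValueError("lower must be <= upper")
    mask = (wth.data >= lower) & (wth.data <= upper)
    return BinaryVolume(mask, wth.spacing)


def fill_holes(b: BinaryVolume) -> BinaryVolume:
    """Fill enclosed cavities: background not 6-connected to the border
    becomes foreground. Foreground never shrinks."""
    return BinaryVolume(ndimage.binary_fill_holes(b.mask), b.spacing)


def label_particles(b: BinaryVolume) -> LabelVolume:
    """Label 26-connected components consecutively from 1."""
    labels, _ = ndimage.label(b.mask, structure=STRUCT_26)
    return LabelVolume(labels, b.spacing)


def _relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    lut = np.zeros(labels.max(initial=0) + 1, dtype=labels.dtype)
    lut[ids] = np.arange(1, len(ids) + 1)
    return lut[labels]


def border_kill(lv: LabelVolume) -> LabelVolume:
    """Remove particles touching any of the six volume faces (incomplete
    objects cut by the field of view); survivors are relabeled from 1."""
    lab = lv.labels
    border_ids = set()
    for axis in range(3):
        for face in (0, -1):
            sl = [slice(None)] * 3
            sl[axis] = face
            border_ids.update(np.unique(lab[tuple(sl)]))
    border_ids.discard(0)
    out = lab.copy()
    if border_ids:
        out[np.isin(out, list(border_ids))] = 0
    return LabelVolume(_relabel_consecutive(out), lv.spacing)


def sieve_volume(
    lv: LabelVolume, min_um3: float, max_um3: float | None = None
) -> LabelVolume:
    """Remove particles by physical volume (voxel count × voxel volume, µm³).

    "Smaller than min" is strict: a particle whose volume equals `min_um3`
    survives; likewise one exactly at `max_um3`.
    """
    if max_um3 is not None and min_um3 > max_um3:
        raise ValueError("min_um3 must be <= max_um3")
    vv = lv.voxel_volume
    out = lv.labels.copy()
    drop = []
    for lab, count in lv.voxel_counts().items():
        vol = count * vv
        if vol < min_um3 or (max_um3 is not None and vol > max_um3):
            drop.append(lab)
    if drop:
        out[np.isin(out, drop)] = 0
    return LabelVolume(_relabel_consecutive(out), lv.spacing)


def nlm_denoise(
    v: IntensityVolume,
    spatial_sd: float = 5.0,
    intensity_sd: float = 0.2,
    search: int = 10,
    patch: int = 3,
) -> IntensityVolume:
    """Non-local means denoising.

    `intensity_sd` is the filtering strength on intensities normalized to
    [0, 1] (so for 16-bit data the effective h is ``intensity_sd × 65535``
    counts); `search` is the half-size of the search window and `patch` the
    patch size, both in voxels. `spatial_sd` is accepted for interface
    compatibility with adaptive-manifold parameterizations but exact
    non-local means has no spatial kernel width; it is ignored.
    """
    if intensity_sd <= 0 or search < 1 or patch < 1:
        raise ValueError("NLM parameters must be positive")
    data = v.data
    info_max = (
        float(np.iinfo(data.dtype).max) if np.issubdtype(data.dtype, np.integer) else None
    )
    scale = info_max if info_max else max(float(data.max()), 1.0)
    norm = data.astype(np.float64) / scale
    out = denoise_nl_means(
        norm, patch_size=patch, patch_distance=search, h=intensity_sd, fast_mode=True
    )
    out = out * scale
    if info_max:
        out = np.clip(np.rint(out), 0, info_max).astype(data.dtype)
    return v.with_data(out, f"NLM denoise h={intensity_sd} search={search} patch={patch}")


def ball_closing(b: BinaryVolume, size: int) -> BinaryVolume:
    """Binary closing (dilation then erosion) with a ball element of radius
    `size` voxels; connects near-touching foreground."""
    if size < 1:
        raise ValueError("size must be >= 1")
    footprint = ball(size)
    closed = ndimage.binary_closing(b.mask, structure=footprint)
    # closing is extensive: never lose original foreground
    return BinaryVolume(closed | b.mask, b.spacing)


def binary_smoothing(b: BinaryVolume, kernel: int = 3, threshold: float = 0.5) -> BinaryVolume:
    """Smooth a mask by thresholding its local mean over a cubic kernel.

    An isolated voxel (local mean 1/27 with kernel 3) falls below the default
    0.5 threshold and is removed; flat interiors are unchanged.
    """
    if kernel < 1:
        raise ValueError("kernel must be >= 1")
    mean = ndimage.uniform_filter(b.mask.astype(np.float64), size=kernel)
    return BinaryVolume(mean >= threshold, b.spacing)


def segment_volume(v: IntensityVolume, params: SegmentationParams) -> LabelVolume:
    """Full µCT segmentation chain: WTH → threshold → fill holes → label →
    border kill → volume sieve. Deterministic given input and parameters."""
    wth = white_top_hat(v, params.wth_kernel, params.wth_element)
    mask = threshold_band(wth, params.wth_lower, params.wth_upper)
    mask = fill_holes(mask)
    lv = label_particles(mask)
    lv = border_kill(lv)
    return sieve_volume(lv, params.min_volume_um3, params.max_volume_um3)
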