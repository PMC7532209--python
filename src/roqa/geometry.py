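"""Tube-source µCT imaging-geometry calculators.

Small planning helpers: the geometric unsharpness (penumbra) of a finite
focal spot, and the Nyquist limit on resolvable feature spacing for a given
voxel size.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ImagingGeometry", "penumbra", "nyquist_min_spacing"]


@dataclass
class ImagingGeometry:
    """Nominal acquisition geometry of a cone-beam micro-CT scan."""

    focal_spot_um: float
    source_to_object_mm: float
    object_to_detector_mm: float
    detector_pixels: int = 2048
    binning: int = 1
    voxel_size_um: float = 1.0

    def __post_init__(self) -> None:
        if min(
            self.focal_spot_um,
            self.source_to_object_mm,
            self.object_to_detector_mm,
            self.voxel_size_um,
        ) <= 0 or self.detector_pixels < 1 or self.binning < 1:
            raise ValueError("all geometry parameters must be positive; binning >= 1")

    @property
    def penumbra_um(self) -> float:
        return penumbra(self.focal_spot_um, self.source_to_object_mm, self.object_to_detector_mm)


def penumbra(focal_spot_um: float, sod_mm: float, odd_mm: float) -> float:
    """Geometric unsharpness at the nominal object plane, in µm.

    A focal spot of finite width *f* projects each object point into a blur
    of width ``f × ODD / SOD`` on the detector, referred back to the object
    plane. ``odd_mm = 0`` is the contact-geometry limit (zero penumbra).
    """
    if focal_spot_um <= 0 or sod_mm <= 0 or odd_mm < 0:
        raise ValueError("focal spot and SOD must be > 0; ODD must be >= 0")
    return focal_spot_um * odd_mm / sod_mm


def nyquist_min_spacing(voxel_um: float) -> float:
    """Smallest resolvable feature spacing under Nyquist sampling: 2 × voxel size."""
    if voxel_um <= 0:
        raise ValueError("voxel size must be > 0")
    return 2.0 * voxel_um
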