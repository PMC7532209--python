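"""Volume and table I/O.

Volumes are 3D scalar grids indexed ``(z, y, x)``, 0-based; "bottom" means the
lowest z index. Physical quantities are carried in µm (spacing), µm²/µm³
(derived measures); intensities stay in native detector counts. RAW volumes
are headerless byte streams and require a JSON sidecar describing shape,
dtype, endianness and spacing — nothing is ever guessed from file size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "IntensityVolume",
    "VolumeMetadata",
    "read_volume",
    "write_volume",
    "crop_bottom_slices",
    "write_records",
    "read_records",
    "RECORD_COLUMNS",
]


@dataclass
class IntensityVolume:
    """A 3D grayscale grid with voxel spacing in µm.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Scalar grid; unsigned 8/16-bit from acquisition, float after
        processing steps that leave the integer range.
    spacing : tuple of float
        Voxel edge lengths ``(dz, dy, dx)`` in µm, all > 0.
    origin : tuple of float
        Physical offset of voxel (0,0,0) in µm.
    provenance : list of str
        Free-text trail of source file and processing steps.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got {self.data.ndim}D")
        if min(self.data.shape) < 1:
            raise ValueError("all volume dimensions must be >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in µm³."""
        dz, dy, dx = self.spacing
        return dz * dy * dx

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray, note: str) -> "IntensityVolume":
        """Derived volume with the same geometry and an appended provenance note."""
        return replace(self, data=data, provenance=[*self.provenance, note])


@dataclass
class VolumeMetadata:
    """Sidecar description sufficient to reinterpret a headerless RAW stream."""

    shape: tuple[int, int, int]
    dtype: str
    endianness: str = "<"
    spacing: tuple[float, float, float] | None = None
    axis_order: str = "zyx"

    def __post_init__(self) -> None:
        self.shape = tuple(int(n) for n in self.shape)
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise ValueError(f"shape must be three positive integers, got {self.shape}")
        if self.endianness not in ("<", ">", "="):
            raise ValueError(f"endianness must be '<', '>' or '=', got {self.endianness!r}")
        if self.axis_order != "zyx":
            raise ValueError("only 'zyx' axis order is supported")
        if self.spacing is not None:
            self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def numpy_dtype(self) -> np.dtype:
        return np.dtype(self.dtype).newbyteorder(self.endianness)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "shape": list(self.shape),
            "dtype": self.dtype,
            "endianness": self.endianness,
            "spacing_um": list(self.spacing) if self.spacing else None,
            "axis_order": self.axis_order,
        }
        Path(path).write_text(json.dumps(doc, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "VolumeMetadata":
        doc = json.loads(Path(path).read_text())
        return cls(
            shape=tuple(doc["shape"]),
            dtype=doc["dtype"],
            endianness=doc.get("endianness", "<"),
            spacing=tuple(doc["spacing_um"]) if doc.get("spacing_um") else None,
            axis_order=doc.get("axis_order", "zyx"),
        )


def _sidecar_path(raw_path: Path) -> Path:
    return raw_path.with_suffix(raw_path.suffix + ".json")


def read_volume(
    path: str | Path,
    metadata: VolumeMetadata | None = None,
    spacing: tuple[float, float, float] | None = None,
) -> IntensityVolume:
    """Read a RAW (+ sidecar) or multi-page TIFF volume.

    RAW files require `metadata` (or a ``<file>.json`` sidecar next to the
    file). TIFF stacks carry shape and dtype internally; spacing comes from
    `spacing` or TIFF resolution tags. A missing spacing is a hard error —
    physical measures downstream depend on it and must never be defaulted.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        if spacing is None:
            raise ValueError(
                f"voxel spacing required to read {path.name}; pass spacing=(dz, dy, dx) in µm"
            )
        return IntensityVolume(data, spacing, provenance=[f"read TIFF {path.name}"])

    if metadata is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise ValueError(f"RAW volume {path.name} needs metadata or sidecar {sidecar.name}")
        metadata = VolumeMetadata.from_json(sidecar)
    eff_spacing = spacing or metadata.spacing
    if eff_spacing is None:
        raise ValueError(f"no voxel spacing declared for {path.name}")
    raw = path.read_bytes()
    dt = metadata.numpy_dtype
    expected = int(np.prod(metadata.shape)) * dt.itemsize
    if len(raw) != expected:
        raise ValueError(
            f"{path.name}: file has {len(raw)} bytes but metadata "
            f"{metadata.shape} {metadata.dtype} implies {expected}"
        )
    data = np.frombuffer(raw, dtype=dt).reshape(metadata.shape)
    return IntensityVolume(data, eff_spacing, provenance=[f"read RAW {path.name}"])


def write_volume(v: IntensityVolume, path: str | Path) -> None:
    """Write a volume as multi-page TIFF or RAW + JSON sidecar (by extension)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, v.data)
        return
    data = np.ascontiguousarray(v.data)
    path.write_bytes(data.tobytes())
    endian = data.dtype.byteorder
    if endian in ("=", "|"):
        endian = "<" if np.little_endian else ">"
    meta = VolumeMetadata(
        shape=data.shape,
        dtype=data.dtype.name,
        endianness=endian,
        spacing=v.spacing,
    )
    meta.to_json(_sidecar_path(path))


def crop_bottom_slices(v: IntensityVolume, thickness_um: float) -> IntensityVolume:
    """Remove ``round(thickness_um / dz)`` slices from the bottom (low-z) face.

    Used to discard reconstruction ring artifacts concentrated near the
    sample holder; e.g. an 88 µm crop at dz = 2.20227 µm removes 40 slices.
    """
    if thickness_um < 0:
        raise ValueError("crop thickness must be >= 0")
    dz = v.spacing[0]
    n = int(round(thickness_um / dz))
    if n == 0:
        return v
    if n >= v.data.shape[0]:
        raise ValueError(
            f"crop of {n} slices covers the whole {v.data.shape[0]}-slice extent"
        )
    return replace(
        v,
        data=v.data[n:],
        provenance=[*v.provenance, f"cropped {n} bottom slices ({thickness_um} µm)"],
    )


#: Column order of the per-particle record table (one row per voxel particle).
RECORD_COLUMNS = [
    "label",
    "voxel_count",
    "voxel_volume_um3",
    "mean_intensity",
    "centroid_z_um",
    "centroid_y_um",
    "centroid_x_um",
    "diameter_longest_um",
    "diameter_medium_um",
    "diameter_shortest_um",
    "flatness",
    "elongation",
    "anisotropy",
    "sphericity",
    "mesh_area_um2",
    "mesh_volume_um3",
    "ellipsoid_volume_um3",
    "ratio",
    "fit_valid",
    "invalid_reason",
    "parent_label",
]


def write_records(records, path: str | Path) -> None:
    """Write shape records to CSV, one row per particle, ordered by label id.

    Missing values (e.g. sphericity for particles whose mesh volume could not
    be computed) are written as empty cells; the row is retained.
    """
    rows = [r.as_dict() for r in records]
    df = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    if len(df):
        df = df.sort_values("label", kind="stable")
    df.to_csv(path, index=False, float_format="%.6g")


def read_records(path: str | Path) -> pd.DataFrame:
    """Read a record table back as a DataFrame."""
    return pd.read_csv(path)
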