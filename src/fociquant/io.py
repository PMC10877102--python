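"""Shared data model and file I/O.

The unit of acquisition is a calibrated single-channel Z-stack per channel
(DAPI for nuclei, 53BP1 for DNA-damage foci), stored as plain multi-page
grayscale TIFF.  Calibration (pixel size, z step) is never inferred from
file metadata alone: it is supplied explicitly and a missing calibration is
an error, not a default.

Coordinate convention: row-major, 0-based ``(row, col)`` everywhere; object
centroids are arithmetic means of member-pixel coordinates.  Connected
components use 8-connectivity in 2D throughout the package.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "Channel",
    "Condition",
    "ZStack",
    "PlaneImage",
    "SemanticMask",
    "LabelMap",
    "ImageMeta",
    "read_zstack",
    "write_zstack",
    "read_mask",
    "write_mask",
    "write_measurements",
    "read_measurements",
]

#: 8-connectivity structuring element shared by every connected-component call.
CONNECTIVITY_2D = 2


class Channel(str, enum.Enum):
    DAPI = "DAPI"
    FOCI = "FOCI"


class Condition(str, enum.Enum):
    CONTROL = "control"
    PHOTON = "photon"
    PROTON = "proton"


def _check_calibration(pixel_size_um: float, z_step_um: float | None = None) -> None:
    if not (pixel_size_um and pixel_size_um > 0):
        raise ValueError(f"pixel_size_um must be > 0, got {pixel_size_um!r}")
    if z_step_um is not None and not (z_step_um > 0):
        raise ValueError(f"z_step_um must be > 0, got {z_step_um!r}")


@dataclass(frozen=True)
class ZStack:
    """Calibrated 3D single-channel intensity volume.

    ``planes`` is a (n_planes, H, W) array ordered by acquisition page
    index; intensities are finite and non-negative but otherwise arbitrary
    (8/16-bit integer and float rasters are accepted uniformly).
    """

    planes: np.ndarray
    pixel_size_um: float
    z_step_um: float
    channel: Channel

    def __post_init__(self) -> None:
        planes = np.asarray(self.planes)
        if planes.ndim != 3 or planes.shape[0] < 1:
            raise ValueError(f"expected (n_planes, H, W) with ≥1 plane, got shape {planes.shape}")
        _check_calibration(self.pixel_size_um, self.z_step_um)
        object.__setattr__(self, "planes", planes)

    @property
    def n_planes(self) -> int:
        return self.planes.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.planes.shape[1:]

    def plane(self, index: int) -> "PlaneImage":
        return PlaneImage(raster=self.planes[index], pixel_size_um=self.pixel_size_um)


@dataclass(frozen=True)
class PlaneImage:
    """A single calibrated 2D intensity raster (selected plane or projection)."""

    raster: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        raster = np.asarray(self.raster)
        if raster.ndim != 2:
            raise ValueError(f"expected 2D raster, got shape {raster.shape}")
        if not np.all(np.isfinite(raster)):
            raise ValueError("intensities must be finite")
        _check_calibration(self.pixel_size_um)
        object.__setattr__(self, "raster", raster)

    @property
    def shape(self) -> tuple[int, int]:
        return self.raster.shape


@dataclass(frozen=True)
class SemanticMask:
    """Binary per-pixel classification (foreground = 1)."""

    raster: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        raster = np.asarray(self.raster)
        if raster.ndim != 2:
            raise ValueError(f"expected 2D mask, got shape {raster.shape}")
        uniq = np.unique(raster)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask values must be in {{0, 1}}, got {uniq[:10]}")
        _check_calibration(self.pixel_size_um)
        object.__setattr__(self, "raster", raster.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.raster.shape


@dataclass(frozen=True)
class LabelMap:
    """Integer-labeled instance map (0 = background, k ≥ 1 = object id).

    Label ids need not be contiguous (sparse ids survive round trips); each
    object is one 8-connected component.
    """

    raster: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        raster = np.asarray(self.raster)
        if raster.ndim != 2:
            raise ValueError(f"expected 2D label map, got shape {raster.shape}")
        if raster.size and raster.min() < 0:
            raise ValueError("label ids must be non-negative")
        _check_calibration(self.pixel_size_um)
        object.__setattr__(self, "raster", raster.astype(np.int32))

    @property
    def shape(self) -> tuple[int, int]:
        return self.raster.shape

    @property
    def labels(self) -> np.ndarray:
        ids = np.unique(self.raster)
        return ids[ids > 0]

    @property
    def n_objects(self) -> int:
        return int(self.labels.size)


@dataclass(frozen=True)
class ImageMeta:
    """Provenance of one acquired image location."""

    patient_id: str
    condition: Condition
    dose_Gy: float
    image_index: int

    def __post_init__(self) -> None:
        if self.dose_Gy < 0:
            raise ValueError("dose_Gy must be ≥ 0")
        if self.condition == Condition.CONTROL and self.dose_Gy != 0:
            raise ValueError("control condition implies dose_Gy = 0")

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.patient_id, self.condition.value, self.image_index)


# ---------------------------------------------------------------------------
# TIFF I/O


def read_zstack(
    path: str | Path,
    pixel_size_um: float,
    z_step_um: float,
    channel: Channel | str,
) -> ZStack:
    """Read a single- or multi-page grayscale TIFF as a calibrated Z-stack.

    Pages are ordered by page index; multi-channel (RGB) pages are rejected.
    """
    _check_calibration(pixel_size_um, z_step_um)
    with tifffile.TiffFile(str(path)) as tif:
        pages = [p.asarray() for p in tif.pages]
    if not pages:
        raise ValueError(f"no image pages in {path}")
    for p in pages:
        if p.ndim != 2:
            raise ValueError(f"expected grayscale pages, got page of shape {p.shape}")
        if p.shape != pages[0].shape:
            raise ValueError("inconsistent page shapes in stack")
    return ZStack(
        planes=np.stack(pages),
        pixel_size_um=float(pixel_size_um),
        z_step_um=float(z_step_um),
        channel=Channel(channel),
    )


def write_zstack(stack: ZStack, path: str | Path) -> Path:
    """Write a Z-stack as a multi-page grayscale TIFF (lossless round trip)."""
    path = Path(path)
    # 3-plane stacks must not be guessed as RGB
    tifffile.imwrite(str(path), stack.planes, photometric="minisblack")
    return path


def write_mask(mask: SemanticMask | LabelMap, path: str | Path) -> Path:
    """Write a mask as TIFF: SemanticMask as 8-bit {0, 255}, LabelMap as 16-bit ids."""
    path = Path(path)
    if isinstance(mask, SemanticMask):
        tifffile.imwrite(str(path), (mask.raster * 255).astype(np.uint8))
    elif isinstance(mask, LabelMap):
        if mask.raster.size and mask.raster.max() > 65535:
            raise ValueError("more than 65535 labels cannot be stored as 16-bit TIFF")
        tifffile.imwrite(str(path), mask.raster.astype(np.uint16))
    else:
        raise TypeError(f"expected SemanticMask or LabelMap, got {type(mask)!r}")
    return path


def read_mask(path: str | Path, pixel_size_um: float, kind: str = "semantic") -> SemanticMask | LabelMap:
    """Read back a mask TIFF written by :func:`write_mask`.

    ``kind`` is ``"semantic"`` (any non-zero pixel → 1) or ``"labels"``.
    """
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise ValueError(f"expected 2D mask, got shape {arr.shape}")
    if kind == "semantic":
        return SemanticMask(raster=(arr > 0).astype(np.uint8), pixel_size_um=pixel_size_um)
    if kind == "labels":
        return LabelMap(raster=arr.astype(np.int32), pixel_size_um=pixel_size_um)
    raise ValueError(f"unknown mask kind {kind!r}")


# ---------------------------------------------------------------------------
# Measurement tables

MEASUREMENT_KEY = ["patient_id", "condition", "image_index", "object_id"]


def write_measurements(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a measurement table (nucleus or focus records) to CSV.

    One row per object, stable column order (key columns first), full float
    precision.  Duplicate ``(patient, condition, image, object)`` keys are an
    error.
    """
    path = Path(path)
    missing = [c for c in MEASUREMENT_KEY if c not in table.columns]
    if missing:
        raise ValueError(f"measurement table lacks key columns {missing}")
    if len(table) and table.duplicated(subset=MEASUREMENT_KEY).any():
        raise ValueError("duplicate measurement keys")
    ordered = MEASUREMENT_KEY + [c for c in table.columns if c not in MEASUREMENT_KEY]
    table[ordered].to_csv(path, index=False, float_format="%.17g")
    return path


def read_measurements(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
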