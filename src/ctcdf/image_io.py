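"""Reading and writing of images, masks, manifests, detection tables.

This module is the single home for the package's encoding and coordinate
conventions:

* images are 8-bit RGB ``uint8`` arrays of shape ``(H, W, 3)``;
* coordinates are ``(row, col)``, 0-based, row 0 at the top;
* bounding boxes are half-open ``[min, max)``;
* masks are boolean ``(H, W)`` arrays, any nonzero source pixel is foreground.

Higher bit depths are linearly rescaled to 8 bits on load because the
illumination correction's histograms assume 256 intensity levels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DETECTION_COLUMNS = [
    "image_id",
    "object_id",
    "centroid_row",
    "centroid_col",
    "area_px",
    "bbox_min_row",
    "bbox_min_col",
    "bbox_max_row",
    "bbox_max_col",
]


@dataclass
class RasterImage:
    """An 8-bit color darkfield frame, the raw input of the pipeline."""

    pixels: np.ndarray  # (H, W, 3) uint8
    id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) pixels, got {self.pixels.shape}")
        if self.pixels.dtype != np.uint8:
            raise ValueError(f"expected uint8 pixels, got {self.pixels.dtype}")
        if self.height < 4 or self.width < 4:
            raise ValueError(
                f"image {self.id!r} is {self.height}x{self.width}; at least 4x4 "
                "is required for the quarter-resolution pyramid level"
            )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class BinaryMask:
    """Boolean ground-truth mask paired with a :class:`RasterImage`."""

    pixels: np.ndarray  # (H, W) bool
    id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected (H, W) mask, got shape {self.pixels.shape}")
        if self.pixels.dtype != bool:
            self.pixels = self.pixels.astype(bool)


@dataclass
class ManifestEntry:
    image: Path
    mask: Path | None
    split: str = ""


@dataclass
class DatasetManifest:
    """Pairs images with ground-truth masks and a train/test split tag."""

    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        paths = [str(e.image) for e in self.entries]
        if len(set(paths)) != len(paths):
            raise ValueError("duplicate image paths in manifest")

    def subset(self, split: str) -> "DatasetManifest":
        return DatasetManifest([e for e in self.entries if e.split == split])

    def __len__(self) -> int:
        return len(self.entries)


def _to_uint8(arr: np.ndarray, path: Path) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr
    arr = arr.astype(np.float64)
    lo, hi = float(arr.min()), float(arr.max())
    logger.warning("rescaling %s from [%g, %g] to 8-bit", path, lo, hi)
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.uint8)
    return np.round((arr - lo) / (hi - lo) * 255.0).astype(np.uint8)


def read_image(path: str | Path) -> RasterImage:
    """Read a PNG/TIFF file as an 8-bit RGB :class:`RasterImage`.

    Grayscale files are replicated to three channels; an alpha channel is
    dropped with a warning; >8-bit data is min/max rescaled to 0-255.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - rewrap with the offending path
        raise IOError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        logger.warning("dropping alpha channel of %s", path)
        arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise IOError(f"cannot interpret {path} with shape {arr.shape} as RGB")
    return RasterImage(pixels=_to_uint8(arr, path), id=path.stem)


def read_mask(path: str | Path, height: int, width: int) -> BinaryMask:
    """Read a ground-truth mask; any pixel > 0 is tumor-cell foreground."""
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"cannot read mask {path}: {exc}") from exc
    if arr.ndim == 3:
        arr = arr[..., :3].max(axis=-1)
    if arr.shape != (height, width):
        raise ValueError(
            f"mask {path} has shape {arr.shape}, expected ({height}, {width})"
        )
    return BinaryMask(pixels=arr > 0, id=path.stem)


def write_image(image: RasterImage, path: str | Path) -> None:
    iio.imwrite(Path(path), image.pixels)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    iio.imwrite(Path(path), mask.pixels.astype(np.uint8) * 255)


def write_detections(objects: Sequence, path: str | Path) -> None:
    """Write detected objects as a CSV table (see :data:`DETECTION_COLUMNS`)."""
    rows = [
        {
            "image_id": o.image_id,
            "object_id": o.object_id,
            "centroid_row": o.centroid[0],
            "centroid_col": o.centroid[1],
            "area_px": o.pixel_count,
            "bbox_min_row": o.bbox[0],
            "bbox_min_col": o.bbox[1],
            "bbox_max_row": o.bbox[2],
            "bbox_max_col": o.bbox[3],
        }
        for o in objects
    ]
    pd.DataFrame(rows, columns=DETECTION_COLUMNS).to_csv(path, index=False)


def read_detections(path: str | Path) -> list:
    from .postprocess import DetectedObject  # local import: avoid cycle

    df = pd.read_csv(path)
    return [
        DetectedObject(
            object_id=int(r.object_id),
            pixel_count=int(r.area_px),
            centroid=(float(r.centroid_row), float(r.centroid_col)),
            bbox=(
                int(r.bbox_min_row),
                int(r.bbox_min_col),
                int(r.bbox_max_row),
                int(r.bbox_max_col),
            ),
            image_id=str(r.image_id),
        )
        for r in df.itertuples()
    ]


def read_manifest(path: str | Path) -> DatasetManifest:
    """Read a dataset manifest CSV with columns ``image,mask,split``.

    Relative paths are resolved against the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("image",):
        if col not in df.columns:
            raise ValueError(f"manifest {path} lacks required column {col!r}")
    base = path.parent
    entries = []
    for r in df.itertuples():
        image = base / str(r.image)
        mask = None
        if "mask" in df.columns and isinstance(r.mask, str) and r.mask:
            mask = base / str(r.mask)
        split = str(r.split) if "split" in df.columns and not pd.isna(r.split) else ""
        entries.append(ManifestEntry(image=image, mask=mask, split=split))
    return DatasetManifest(entries)


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    path = Path(path)
    base = path.parent
    rows = []
    for e in manifest.entries:
        rows.append(
            {
                "image": _relativize(e.image, base),
                "mask": _relativize(e.mask, base) if e.mask is not None else "",
                "split": e.split,
            }
        )
    pd.DataFrame(rows, columns=["image", "mask", "split"]).to_csv(path, index=False)


def _relativize(p: Path, base: Path) -> str:
    try:
        return str(Path(p).relative_to(base))
    except ValueError:
        return str(p)
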