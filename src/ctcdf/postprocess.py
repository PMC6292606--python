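"""From per-pixel tumor masks to validated object detections.

The raw pixel classifier output is cleaned by a morphological opening (which
removes speck-sized false positives), connected pixel groups are labeled with
8-connectivity, and a group is validated as a CTC only if its area strictly
exceeds ``min_area`` pixels (default 100).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_opening
from skimage.measure import label as _sk_label, regionprops
from skimage.morphology import disk

from .image_io import BinaryMask

DEFAULT_MIN_AREA = 100
DEFAULT_OPENING_RADIUS = 2


@dataclass
class DetectedObject:
    """A connected pixel group; the unit counted as a CTC.

    ``bbox`` is half-open ``(min_row, min_col, max_row, max_col)``.  The
    ``pixels`` field (an (A, 2) coordinate array) is carried for overlap-based
    matching against ground truth and is not serialized to CSV.
    """

    object_id: int
    pixel_count: int
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]
    image_id: str = ""
    pixels: np.ndarray | None = field(default=None, repr=False, compare=False)


def morphological_clean(mask: BinaryMask, radius: int = DEFAULT_OPENING_RADIUS) -> BinaryMask:
    """Binary opening (erosion then dilation) with a discrete disk.

    Radius 0 is the identity.  Opening is anti-extensive and idempotent, so it
    only ever removes pixels and a second application changes nothing.  Pixels
    outside the image count as background for the erosion step.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return BinaryMask(pixels=mask.pixels.copy(), id=mask.id)
    opened = binary_opening(mask.pixels, structure=disk(radius).astype(bool))
    return BinaryMask(pixels=opened, id=mask.id)


def label_components(mask: BinaryMask) -> list[DetectedObject]:
    """8-connected components as objects, ids 1..K in raster-scan order."""
    labels = _sk_label(mask.pixels, connectivity=2)
    objects = []
    for prop in regionprops(labels):
        min_row, min_col, max_row, max_col = prop.bbox
        objects.append(
            DetectedObject(
                object_id=int(prop.label),
                pixel_count=int(prop.area),
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                bbox=(int(min_row), int(min_col), int(max_row), int(max_col)),
                image_id=mask.id,
                pixels=np.asarray(prop.coords),
            )
        )
    objects.sort(key=lambda o: o.object_id)
    return objects


def validate_objects(
    objects: list[DetectedObject], min_area: int = DEFAULT_MIN_AREA
) -> list[DetectedObject]:
    """Keep objects whose area is strictly greater than ``min_area``."""
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    return [o for o in objects if o.pixel_count > min_area]


def detect_objects(
    mask: BinaryMask,
    opening_radius: int = DEFAULT_OPENING_RADIUS,
    min_area: int = DEFAULT_MIN_AREA,
) -> list[DetectedObject]:
    """Full post-processing chain: open, label, area-validate."""
    cleaned = morphological_clean(mask, opening_radius)
    return validate_objects(label_components(cleaned), min_area)


def label_image(objects: list[DetectedObject], shape: tuple[int, int]) -> np.ndarray:
    """Render validated objects back into a 16-bit label image."""
    out = np.zeros(shape, dtype=np.uint16)
    for o in objects:
        if o.pixels is None:
            raise ValueError(f"object {o.object_id} carries no pixel coordinates")
        out[o.pixels[:, 0], o.pixels[:, 1]] = o.object_id
    return out
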