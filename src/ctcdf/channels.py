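"""Multi-resolution channel features for darkfield pixel classification.

A "channel" is a per-pixel transform of the corrected input frame.  Five
channels are computed at each of three resolutions (full, half, quarter):

* ``L``, ``u``, ``v`` — the CIE 1976 L*u*v* color coordinates (sRGB primaries,
  D65 white point).  L*u*v* is approximately perceptually uniform and keeps
  chromaticity separate from luminance, which matters under the colored glow
  of darkfield artifacts.
* gradient magnitude of ``L`` (Sobel 3x3, replicated borders);
* gradient orientation of ``L``, quantized to 8 codes at 45-degree spacing.

Coarser levels are built by repeated 2x2 mean pooling of the L/u/v grids
(the average-pooling analogy of a CNN); gradients are recomputed at each
level rather than pooled, so coarse orientation reflects coarse structure.

A per-pixel feature vector samples every channel at the anchor pixel and at a
ring pattern of neighbor offsets sized to the expected tumor-cell diameter,
giving the classifier a fixed-length texture descriptor of the cell area.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
from skimage.color import rgb2luv

from .image_io import RasterImage

N_LEVELS = 3
CHANNELS_PER_LEVEL = 5
N_CHANNELS = N_LEVELS * CHANNELS_PER_LEVEL
LEVEL_SCALES = (1, 2, 4)
N_ORIENT = 8


@dataclass(frozen=True)
class NeighborhoodPattern:
    """Ordered neighbor displacements sampled around each anchor pixel.

    The anchor ``(0, 0)`` is always implicitly the first sample point and
    must not be listed among the offsets.
    """

    offsets: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if (0, 0) in self.offsets:
            raise ValueError("(0, 0) is implicit and must not appear in offsets")
        if len(set(self.offsets)) != len(self.offsets):
            raise ValueError("duplicate offsets in pattern")

    @property
    def n_samples(self) -> int:
        return 1 + len(self.offsets)

    @property
    def r_max(self) -> int:
        if not self.offsets:
            return 0
        return max(max(abs(dr), abs(dc)) for dr, dc in self.offsets)

    def to_dict(self) -> dict:
        return {"offsets": [list(o) for o in self.offsets]}

    @classmethod
    def from_dict(cls, d: dict) -> "NeighborhoodPattern":
        return cls(offsets=tuple(tuple(o) for o in d["offsets"]))


def default_pattern(cell_diameter_px: float = 40.0) -> NeighborhoodPattern:
    """Two concentric 8-point rings covering the expected cell area.

    Ring radii are ``round(diameter/4)`` and ``round(diameter/2)`` with
    45-degree angular spacing, rounded to integer displacements (duplicates
    dropped), so the pattern spans from the cell interior to its rim.
    """
    if cell_diameter_px < 4:
        raise ValueError("cell diameter must be at least 4 px")
    offsets: list[tuple[int, int]] = []
    for radius in (round(cell_diameter_px / 4), round(cell_diameter_px / 2)):
        for k in range(8):
            a = math.radians(45.0 * k)
            off = (round(radius * math.sin(a)), round(radius * math.cos(a)))
            if off != (0, 0) and off not in offsets:
                offsets.append(off)
    return NeighborhoodPattern(offsets=tuple(offsets))


@dataclass
class ChannelStack:
    """15 feature channels of one frame: 5 channels x 3 resolution levels.

    ``levels[s]`` is a list ``[L, u, v, grad_mag, grad_orient]`` of 2-D arrays
    at scale factor ``LEVEL_SCALES[s]``.
    """

    levels: list[list[np.ndarray]]
    image_id: str = ""

    @property
    def full_shape(self) -> tuple[int, int]:
        return self.levels[0][0].shape

    def channel(self, level: int, index: int) -> np.ndarray:
        return self.levels[level][index]


def rgb_to_luv(image: RasterImage) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """CIE L*u*v* (D65, sRGB) grids of an 8-bit RGB image; L in [0, 100]."""
    luv = rgb2luv(image.pixels)
    return luv[:, :, 0], luv[:, :, 1], luv[:, :, 2]


def gradient(image_gray: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sobel gradient magnitude and 8-way quantized orientation.

    The angle convention is image-standard with row increasing downward, so
    the reported angle is ``atan2(-g_row, g_col)`` mapped to [0, 360); code
    ``k`` covers angles nearest ``45k`` degrees, ties toward the smaller code.
    Zero-gradient pixels get code 0.
    """
    image_gray = np.asarray(image_gray, dtype=np.float64)
    if image_gray.shape[0] < 3 or image_gray.shape[1] < 3:
        raise ValueError(f"gradient needs a grid of at least 3x3, got {image_gray.shape}")
    g_row = ndi.sobel(image_gray, axis=0, mode="nearest")
    g_col = ndi.sobel(image_gray, axis=1, mode="nearest")
    mag = np.hypot(g_col, g_row)
    angle = np.degrees(np.arctan2(-g_row, g_col)) % 360.0
    # nearest multiple of 45 deg, ties toward the smaller code
    codes = np.ceil(angle / 45.0 - 0.5).astype(np.int64) % N_ORIENT
    codes[mag == 0] = 0
    return mag, codes


def downsample(grid: np.ndarray) -> np.ndarray:
    """Non-overlapping 2x2 mean pooling; a trailing odd row/col is dropped."""
    grid = np.asarray(grid, dtype=np.float64)
    H, W = grid.shape
    if H < 2 or W < 2:
        raise ValueError(f"cannot downsample a {H}x{W} grid")
    h, w = H // 2, W // 2
    return grid[: 2 * h, : 2 * w].reshape(h, 2, w, 2).mean(axis=(1, 3))


def compute_channel_stack(image: RasterImage) -> ChannelStack:
    """Build the full 15-channel stack of an (illumination-corrected) frame."""
    L, u, v = rgb_to_luv(image)
    levels = []
    for level in range(N_LEVELS):
        if level > 0:
            L, u, v = downsample(L), downsample(u), downsample(v)
        mag, orient = gradient(L)
        levels.append([L, u, v, mag, orient.astype(np.float64)])
    return ChannelStack(levels=levels, image_id=image.id)


def extract_feature_matrix(
    stack: ChannelStack,
    anchors: np.ndarray,
    pattern: NeighborhoodPattern,
) -> np.ndarray:
    """Feature vectors for many anchors at once.

    Parameters
    ----------
    anchors : (N, 2) integer array of full-resolution (row, col) positions.

    Returns
    -------
    (N, 15 * n_samples) float array.  Layout is level-major, channel-minor:
    for each level, for each of its 5 channels, the anchor sample followed by
    the pattern offsets in order.  Neighbor coordinates are divided by the
    level scale with floor and clamped to the grid.
    """
    anchors = np.asarray(anchors, dtype=np.int64)
    if anchors.ndim != 2 or anchors.shape[1] != 2:
        raise ValueError("anchors must be an (N, 2) array")
    H, W = stack.full_shape
    if anchors.size and (
        anchors.min() < 0 or anchors[:, 0].max() >= H or anchors[:, 1].max() >= W
    ):
        raise ValueError("anchors must lie inside the full-resolution image")
    sample_offsets = [(0, 0), *pattern.offsets]
    n = anchors.shape[0]
    out = np.empty((n, N_CHANNELS * len(sample_offsets)), dtype=np.float64)
    col = 0
    for level, scale in enumerate(LEVEL_SCALES):
        h, w = stack.levels[level][0].shape
        coords = []
        for dr, dc in sample_offsets:
            rr = np.clip((anchors[:, 0] + dr) // scale, 0, h - 1)
            cc = np.clip((anchors[:, 1] + dc) // scale, 0, w - 1)
            coords.append((rr, cc))
        for chan in stack.levels[level]:
            for rr, cc in coords:
                out[:, col] = chan[rr, cc]
                col += 1
    return out


def extract_feature_vector(
    stack: ChannelStack,
    anchor: tuple[int, int],
    pattern: NeighborhoodPattern,
) -> np.ndarray:
    """Feature vector of a single anchor pixel (see extract_feature_matrix)."""
    return extract_feature_matrix(stack, np.array([anchor]), pattern)[0]


def feature_dimension(pattern: NeighborhoodPattern) -> int:
    return N_CHANNELS * pattern.n_samples


def describe_feature(index: int, pattern: NeighborhoodPattern) -> dict:
    """Map a flat feature index back to (level, channel, sample offset)."""
    n_s = pattern.n_samples
    level, rem = divmod(index, CHANNELS_PER_LEVEL * n_s)
    channel, sample = divmod(rem, n_s)
    names = ["L", "u", "v", "grad_mag", "grad_orient"]
    offset = (0, 0) if sample == 0 else pattern.offsets[sample - 1]
    return {"level": level, "channel": names[channel], "offset": offset}
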