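"""Windowed histogram-mode illumination correction for darkfield frames.

Darkfield images have a near-black background, so the dominant histogram bin
of any local window should sit at intensity zero.  Reflective debris on the
cover glass produces large out-of-focus halos that lift the local background;
uneven cell density shifts overall brightness.  The correction estimates the
local background as the *mode* of the intensity histogram of each
``wsize x wsize`` window, interpolates the per-window modes bilinearly into a
full-resolution background mask, and subtracts the mask from the image
(clamping at zero), which drags every local background back to black.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_io import RasterImage

N_BINS = 256


@dataclass(frozen=True)
class IlluminationConfig:
    """Parameters of the windowed background estimate.

    wsize
        Window side length in pixels.  Must be small relative to halo
        artifacts (so the mask can follow them) but large relative to single
        blood cells (so the window mode stays background, not cell).
    stride
        Spacing between window origins.  The default, half a window, gives
        overlapping windows whose interpolated mask tracks the curvature of
        large halos to within about one intensity level; ``stride == wsize``
        reproduces a plain non-overlapping tiling.
    """

    wsize: int = 64
    stride: int | None = None  # None -> wsize // 2
    n_bins: int = N_BINS

    @property
    def stride_effective(self) -> int:
        return self.stride if self.stride is not None else max(1, self.wsize // 2)

    def validate_for(self, height: int, width: int) -> None:
        if self.wsize < 8:
            raise ValueError(f"wsize must be >= 8, got {self.wsize}")
        if self.wsize > min(height, width):
            raise ValueError(
                f"wsize={self.wsize} exceeds image extent {height}x{width}"
            )
        if self.n_bins != N_BINS:
            raise ValueError("only 256-bin (8-bit) histograms are supported")
        if self.stride_effective < 1 or self.stride_effective > self.wsize:
            raise ValueError("stride must be in [1, wsize]")


@dataclass
class IlluminationMask:
    """Estimated background level per pixel (piecewise-bilinear, in [0, 255])."""

    pixels: np.ndarray


def window_mode(channel: np.ndarray, origin: tuple[int, int], wsize: int) -> int:
    """Histogram mode of one ``wsize x wsize`` window.

    The window starts at ``origin`` and is clipped to the image boundary.
    Ties between equally tall bins break toward the *lowest* intensity, which
    biases the estimate toward true black background.
    """
    r0, c0 = origin
    window = channel[r0 : r0 + wsize, c0 : c0 + wsize]
    if window.size == 0:
        raise ValueError(f"empty window at origin {origin} with wsize {wsize}")
    counts = np.bincount(
        np.asarray(window, dtype=np.uint8).ravel(), minlength=N_BINS
    )
    return int(counts.argmax())  # argmax returns the first = lowest level


def _window_starts(extent: int, stride: int) -> np.ndarray:
    return np.arange(0, extent, stride)


def build_mask(channel: np.ndarray, config: IlluminationConfig) -> IlluminationMask:
    """Estimate the per-pixel background of one image channel.

    Window modes are computed on a regular grid of ``wsize x wsize`` windows
    (origin spacing ``config.stride_effective``, border windows clipped),
    anchored at each window's center, and interpolated bilinearly; outside
    the convex hull of anchors the nearest anchor value is used.
    """
    channel = np.asarray(channel)
    H, W = channel.shape
    config.validate_for(H, W)
    w = config.wsize
    row_starts = _window_starts(H, config.stride_effective)
    col_starts = _window_starts(W, config.stride_effective)
    # anchor coordinate = center of the (possibly clipped) window
    row_anchor = np.array([(r + min(r + w, H) - 1) / 2.0 for r in row_starts])
    col_anchor = np.array([(c + min(c + w, W) - 1) / 2.0 for c in col_starts])
    modes = np.empty((len(row_starts), len(col_starts)), dtype=np.float64)
    for i, r in enumerate(row_starts):
        for j, c in enumerate(col_starts):
            modes[i, j] = window_mode(channel, (r, c), w)

    rr = np.clip(np.arange(H, dtype=np.float64), row_anchor[0], row_anchor[-1])
    cc = np.clip(np.arange(W, dtype=np.float64), col_anchor[0], col_anchor[-1])
    # separable bilinear interpolation on the (possibly 1-node) anchor grid
    mask = _interp_grid(modes, row_anchor, rr, axis=0)
    mask = _interp_grid(mask, col_anchor, cc, axis=1)
    return IlluminationMask(pixels=mask)


def _interp_grid(values: np.ndarray, xp: np.ndarray, x: np.ndarray, axis: int) -> np.ndarray:
    if len(xp) == 1:
        shape = list(values.shape)
        reps = [1, 1]
        reps[axis] = len(x)
        shape[axis] = 1
        return np.tile(values.reshape(shape), reps)
    out = np.apply_along_axis(lambda v: np.interp(x, xp, v), axis, values)
    return out


def correct_illumination(
    image: RasterImage, config: IlluminationConfig | None = None
) -> RasterImage:
    """Subtract the estimated background mask from each color channel.

    ``I_dst = clamp(I_src - I_mask, 0, 255)`` per channel; the mask is built
    independently for each of the three channels so that colored artifact glow
    is compensated channel by channel.
    """
    config = config or IlluminationConfig()
    out = np.empty_like(image.pixels)
    for c in range(3):
        mask = build_mask(image.pixels[:, :, c], config)
        corrected = image.pixels[:, :, c].astype(np.float64) - mask.pixels
        out[:, :, c] = np.clip(np.round(corrected), 0, 255).astype(np.uint8)
    return RasterImage(pixels=out, id=image.id)
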