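"""Synthetic darkfield blood scenes with paired tumor-cell ground truth.

The generator emulates the statistical structure of darkfield frames of
unstained blood spiked with cultured tumor cells:

* a near-black background with sensor noise;
* many small, bright, smooth blood cells with a slightly cool hue — on the
  order of 1270 cells per full 2048x1088 camera frame, scaled to the canvas
  by area;
* a few large tumor cells with an irregular (radially perturbed) contour, a
  brighter rim, a warm hue, and strong internal speckle texture — the
  morphological signature that makes them separable from blood cells;
* optional large, smooth, bright halos from out-of-focus cover-glass debris,
  which corrupt local illumination the way real artifacts do.

The ground-truth mask is true exactly on tumor-cell pixels.  Tumor cells are
kept disjoint from each other and from blood cells by rejection sampling, so
the mask has exactly ``n_tumor`` connected components.  Everything is
reproducible from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .image_io import (
    BinaryMask,
    DatasetManifest,
    ManifestEntry,
    RasterImage,
    write_image,
    write_manifest,
    write_mask,
)

# full camera frame of the acquisition setup being emulated
FRAME_CELLS = 1270.0
FRAME_AREA = 2048 * 1088

TUMOR_TINT = np.array([1.0, 0.88, 0.62])  # warm
BLOOD_TINT = np.array([0.78, 0.88, 1.0])  # cool
HALO_TINT = np.array([1.0, 0.97, 0.90])

MAX_BOUNDARY_PERTURBATION = 0.35  # bound on the radial contour modulation


@dataclass(frozen=True)
class SceneParams:
    """Generation parameters for one synthetic frame.

    ``n_blood=None`` scales the 1270-cells-per-frame average to the canvas
    area.  ``tumor_texture_contrast`` multiplies the tumor-interior speckle
    standard deviation (1.0 = default separability).
    """

    height: int = 512
    width: int = 512
    n_tumor: int = 4
    tumor_diameter_px: tuple[float, float] = (40.0, 4.0)  # mean, sd
    tumor_texture_contrast: float = 1.0
    n_blood: int | None = None
    blood_diameter_px: tuple[float, float] = (10.0, 1.5)
    artifact_halos: int = 1
    background_level: int = 8
    noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tumor_diameter_px[0] <= self.blood_diameter_px[0]:
            raise ValueError("tumor cells must be larger than blood cells")
        if not 0 <= self.background_level < 20:
            raise ValueError("darkfield background must be near-black (< 20)")
        if self.height < 16 or self.width < 16:
            raise ValueError("canvas too small")

    @property
    def n_blood_effective(self) -> int:
        if self.n_blood is not None:
            return self.n_blood
        return int(round(FRAME_CELLS * (self.height * self.width) / FRAME_AREA))


@dataclass
class SceneObject:
    kind: str  # "tumor" | "blood"
    center: tuple[float, float]
    radius: float


def _place(
    rng: np.random.Generator,
    H: int,
    W: int,
    radius: float,
    placed: list[SceneObject],
    clearance: float,
    max_tries: int = 400,
) -> tuple[float, float]:
    for _ in range(max_tries):
        r = rng.uniform(radius, H - radius)
        c = rng.uniform(radius, W - radius)
        ok = True
        for o in placed:
            if math.hypot(r - o.center[0], c - o.center[1]) < clearance + o.radius + radius:
                ok = False
                break
        if ok:
            return r, c
    raise RuntimeError(
        "could not place an object without overlap after "
        f"{max_tries} tries; lower the object density"
    )


def _render_tumor(
    canvas: np.ndarray,
    mask: np.ndarray,
    rng: np.random.Generator,
    center: tuple[float, float],
    radius: float,
    texture_contrast: float,
) -> None:
    H, W = mask.shape
    pad = int(math.ceil(radius * (1 + MAX_BOUNDARY_PERTURBATION))) + 2
    r0, r1 = max(0, int(center[0]) - pad), min(H, int(center[0]) + pad + 1)
    c0, c1 = max(0, int(center[1]) - pad), min(W, int(center[1]) + pad + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dy = rr - center[0]
    dx = cc - center[1]
    rho = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    # irregular contour: low-order Fourier modulation of the radius
    boundary = np.full_like(theta, radius)
    for k in range(2, 6):
        a = rng.uniform(-0.08, 0.08)
        phi = rng.uniform(0, 2 * math.pi)
        boundary = boundary + radius * a * np.cos(k * theta + phi)
    inside = rho <= boundary
    base = rng.uniform(110.0, 170.0)
    rel = np.divide(rho, boundary, out=np.ones_like(rho), where=boundary > 0)
    rim = 45.0 * np.exp(-((rel - 0.93) ** 2) / (2 * 0.05**2))
    # per-cell tint jitter and per-channel speckle: hue is informative but
    # not a clean per-pixel label, as in label-free scattering
    tint = TUMOR_TINT * rng.uniform(0.92, 1.08, size=3)
    speckle = rng.normal(
        0.0, 35.0 * texture_contrast, size=(*rho.shape, 3)
    )
    patch = (base + rim)[..., None] * tint + speckle
    patch = np.where(inside[..., None], patch, 0.0)
    canvas[r0:r1, c0:c1] += np.clip(patch, 0, None)
    mask[r0:r1, c0:c1] |= inside


def _render_blood(
    canvas: np.ndarray,
    rng: np.random.Generator,
    center: tuple[float, float],
    radius: float,
) -> None:
    H = canvas.shape[0]
    W = canvas.shape[1]
    pad = int(math.ceil(radius)) + 2
    r0, r1 = max(0, int(center[0]) - pad), min(H, int(center[0]) + pad + 1)
    c0, c1 = max(0, int(center[1]) - pad), min(W, int(center[1]) + pad + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    rho = np.hypot(rr - center[0], cc - center[1])
    rel = rho / radius
    peak = rng.uniform(140.0, 220.0)
    # near-flat bright interior with a brighter rim at the membrane and a
    # soft edge; the smooth interior is what separates blood from the
    # speckled tumor texture
    profile = 0.55 + 0.45 * np.exp(-((rel - 0.88) ** 2) / (2 * 0.10**2))
    soft = np.clip((1.05 - rel) / 0.15, 0.0, 1.0)
    intensity = np.where(rel <= 1.05, peak * profile * soft, 0.0)
    tint = BLOOD_TINT * rng.uniform(0.92, 1.08, size=3)
    canvas[r0:r1, c0:c1] += intensity[..., None] * tint


def _render_halo(
    canvas: np.ndarray, rng: np.random.Generator, H: int, W: int
) -> None:
    center = (rng.uniform(0, H), rng.uniform(0, W))
    # halos vary slowly at the correction-window scale: out-of-focus debris
    # glow is smooth, and the windowed-mode background estimate is only
    # meaningful when the glow is near-flat within one window
    sigma = rng.uniform(100.0, 160.0)
    amplitude = rng.uniform(25.0, 45.0)
    rr, cc = np.mgrid[0:H, 0:W]
    g = amplitude * np.exp(
        -((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / (2 * sigma**2)
    )
    canvas += g[..., None] * HALO_TINT


def generate_scene(
    params: SceneParams,
) -> tuple[RasterImage, BinaryMask, list[SceneObject]]:
    """Render one synthetic darkfield frame with its ground-truth mask."""
    rng = np.random.default_rng(params.seed)
    H, W = params.height, params.width
    canvas = np.zeros((H, W, 3), dtype=np.float64)
    mask = np.zeros((H, W), dtype=bool)
    objects: list[SceneObject] = []

    tumors: list[SceneObject] = []
    for _ in range(params.n_tumor):
        d = max(8.0, rng.normal(*params.tumor_diameter_px))
        radius = d / 2.0
        center = _place(rng, H, W, radius * (1 + MAX_BOUNDARY_PERTURBATION), tumors, clearance=6.0)
        obj = SceneObject("tumor", center, radius)
        tumors.append(obj)
        objects.append(obj)
        _render_tumor(canvas, mask, rng, center, radius, params.tumor_texture_contrast)

    # blood cells must stay clear of tumor cells (ground truth is tumor-only);
    # blood-blood contact is allowed, as in a real smear
    tumor_keepout = [
        replace_radius(o, o.radius * (1 + MAX_BOUNDARY_PERTURBATION) + 3) for o in tumors
    ]
    for _ in range(params.n_blood_effective):
        d = max(4.0, rng.normal(*params.blood_diameter_px))
        radius = d / 2.0
        center = _place(rng, H, W, radius, tumor_keepout, clearance=0.0)
        objects.append(SceneObject("blood", center, radius))
        _render_blood(canvas, rng, center, radius)

    for _ in range(params.artifact_halos):
        _render_halo(canvas, rng, H, W)

    canvas += params.background_level
    canvas += rng.normal(0.0, params.noise_sd, size=canvas.shape)
    pixels = np.clip(np.round(canvas), 0, 255).astype(np.uint8)
    return (
        RasterImage(pixels=pixels, id=f"scene_{params.seed}"),
        BinaryMask(pixels=mask, id=f"scene_{params.seed}"),
        objects,
    )


def replace_radius(obj: SceneObject, radius: float) -> SceneObject:
    return SceneObject(kind=obj.kind, center=obj.center, radius=radius)


def interior_variance(image: RasterImage, obj: SceneObject) -> float:
    """Luminance variance inside the central 60% of a scene object."""
    H, W = image.height, image.width
    rr, cc = np.mgrid[0:H, 0:W]
    rho = np.hypot(rr - obj.center[0], cc - obj.center[1])
    sel = rho <= 0.6 * obj.radius
    gray = image.pixels.astype(np.float64).mean(axis=2)
    return float(gray[sel].var())


def generate_dataset(
    n_images: int,
    params: SceneParams,
    out_dir: str | Path,
    seed: int | None = None,
    train_fraction: float = 0.7,
    tumor_count_range: tuple[int, int] | None = (3, 5),
) -> DatasetManifest:
    """Write ``n_images`` image/mask pairs plus a manifest with split tags.

    Per-image seeds are ``seed + i``; the first ``round(train_fraction * n)``
    images are tagged ``train``, the rest ``test``.  When
    ``tumor_count_range`` is given, the tumor count of each frame is drawn
    uniformly from it (inclusive).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base_seed = params.seed if seed is None else seed
    n_train = int(round(train_fraction * n_images))
    entries = []
    for i in range(n_images):
        scene_seed = base_seed + i
        p = replace(params, seed=scene_seed)
        if tumor_count_range is not None:
            lo, hi = tumor_count_range
            count_rng = np.random.default_rng(
                np.random.SeedSequence(entropy=scene_seed, spawn_key=(1,))
            )
            p = replace(p, n_tumor=int(count_rng.integers(lo, hi + 1)))
        image, mask, _ = generate_scene(p)
        img_name = f"image_{i:03d}.png"
        mask_name = f"mask_{i:03d}.png"
        write_image(image, out_dir / img_name)
        write_mask(mask, out_dir / mask_name)
        entries.append(
            ManifestEntry(
                image=out_dir / img_name,
                mask=out_dir / mask_name,
                split="train" if i < n_train else "test",
            )
        )
    manifest = DatasetManifest(entries)
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest
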