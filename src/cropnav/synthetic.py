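"""Parametric synthetic farmland scenes with exact ground truth.

Overhead field imagery of row crops is emulated as near-parallel sown bands
(crop rows) on a soil background, with the nuisance factors real field
acquisitions vary over: boundary raggedness of the canopy, scattered weed
blobs, a shading gradient and a crop growth stage that controls canopy
width and texture density.  Every scene carries its exact row centerlines,
so both the segmentation network and the line-fitting stage can be scored
against known truth without any external dataset.

Coordinates are 0-based with x = column (rightward) and y = row (downward).
Row centerlines are parameterised by their abscissas at the top (y = 0) and
bottom (y = H-1) image rows, which stays well-conditioned for the
near-vertical rows that dominate row-crop imagery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import ParameterError

__all__ = [
    "FieldSceneParams",
    "GroundTruthLine",
    "FieldSample",
    "generate_scene",
    "generate_dataset",
    "write_dataset",
    "child_seed",
]

# Rendering palette (RGB). Crop and weed greens are deliberately close so
# weeds act as distractors for the segmentation network.
_SOIL_RGB = np.array([112.0, 86.0, 60.0])
_CROP_RGB = np.array([62.0, 128.0, 52.0])
_WEED_RGB = np.array([78.0, 140.0, 70.0])


@dataclass(frozen=True)
class FieldSceneParams:
    """Geometry and nuisance parameters of one synthetic field scene.

    ``row_angle`` is measured in degrees from the image vertical; positive
    angles lean the rows rightward going down the image.  ``jaggedness`` is
    the standard deviation (pixels) of independent per-scanline noise on each
    band edge.  ``weed_density`` is the expected number of weed blobs per
    10^4 px^2.  ``growth_stage`` in [0, 1] scales the effective band width
    (half width at 0, full ``row_width`` at 1) and the canopy texture
    density.
    """

    image_height: int = 512
    image_width: int = 512
    n_rows: int = 4
    row_spacing: int = 110
    row_width: int = 30
    row_angle: float = 0.0
    jaggedness: float = 2.0
    weed_density: float = 0.5
    weed_radius_range: tuple[int, int] = (2, 5)
    shade_fraction: float = 0.3
    growth_stage: float = 1.0

    def validate(self) -> None:
        if self.image_height <= 0:
            raise ParameterError("image_height must be positive")
        if self.image_width <= 0:
            raise ParameterError("image_width must be positive")
        if self.n_rows < 1:
            raise ParameterError("n_rows must be >= 1")
        if not self.row_width > 0:
            raise ParameterError("row_width must be positive")
        if not self.row_spacing > self.row_width:
            raise ParameterError("row_spacing must exceed row_width")
        if self.jaggedness < 0:
            raise ParameterError("jaggedness must be non-negative")
        if self.weed_density < 0:
            raise ParameterError("weed_density must be non-negative")
        lo, hi = self.weed_radius_range
        if lo < 1 or hi < lo:
            raise ParameterError("weed_radius_range must satisfy 1 <= min <= max")
        if not 0.0 <= self.shade_fraction <= 1.0:
            raise ParameterError("shade_fraction must lie in [0, 1]")
        if not 0.0 <= self.growth_stage <= 1.0:
            raise ParameterError("growth_stage must lie in [0, 1]")
        if abs(self.row_angle) >= 60.0:
            raise ParameterError("row_angle must stay within (-60, 60) degrees of vertical")

    def with_(self, **kwargs) -> "FieldSceneParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class GroundTruthLine:
    """A row centerline as the segment joining (x0, 0) and (x1, H-1)."""

    x0: float
    x1: float

    def abscissa_at(self, y: float, image_height: int) -> float:
        if image_height <= 1:
            return self.x0
        t = y / (image_height - 1)
        return (1.0 - t) * self.x0 + t * self.x1

    def direction(self, image_height: int) -> np.ndarray:
        v = np.array([self.x1 - self.x0, float(image_height - 1)])
        return v / np.linalg.norm(v)


@dataclass
class FieldSample:
    """One rendered scene: RGB image, binary crop mask, true centerlines."""

    image: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray  # (H, W) uint8 in {0, 1}
    gt_lines: list[GroundTruthLine] = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


def _row_centers(params: FieldSceneParams) -> np.ndarray:
    mid = (params.image_width - 1) / 2.0
    offsets = (np.arange(params.n_rows) - (params.n_rows - 1) / 2.0) * params.row_spacing
    return mid + offsets


def _effective_width(params: FieldSceneParams) -> int:
    return max(1, int(round(params.row_width * (0.5 + 0.5 * params.growth_stage))))


def generate_scene(params: FieldSceneParams, seed: int) -> FieldSample:
    """Render one field scene deterministically from ``(params, seed)``.

    The mask marks sown rows only; weed blobs and shading perturb the
    rendered image but never the mask or the ground-truth lines.
    """
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    h, w = params.image_height, params.image_width
    ys = np.arange(h, dtype=np.float64)
    centers = _row_centers(params)
    slope = np.tan(np.radians(params.row_angle))
    width = _effective_width(params)

    # Edge noise is drawn up front with a growth-independent layout so the
    # same seed yields nested masks as growth_stage increases.
    edge_noise = rng.normal(0.0, params.jaggedness, size=(params.n_rows, 2, h)) if params.jaggedness > 0 else np.zeros((params.n_rows, 2, h))

    mask = np.zeros((h, w), dtype=bool)
    cols = np.arange(w)
    gt_lines: list[GroundTruthLine] = []
    y_mid = (h - 1) / 2.0
    for i, xc in enumerate(centers):
        center_y = xc + (ys - y_mid) * slope
        # pixel x belongs to the band iff x lies in [left, right): an interval
        # of integer length always covers exactly `width` pixels at zero noise
        left = center_y - width / 2.0 + edge_noise[i, 0]
        right = center_y + width / 2.0 + edge_noise[i, 1]
        mask |= (cols[None, :] >= left[:, None]) & (cols[None, :] < right[:, None])
        gt_lines.append(
            GroundTruthLine(x0=xc + (0 - y_mid) * slope, x1=xc + (h - 1 - y_mid) * slope)
        )

    mask = mask.astype(np.uint8)
    image = _render_image(params, mask, rng)
    return FieldSample(image=image, mask=mask, gt_lines=gt_lines)


def _render_image(params: FieldSceneParams, mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    h, w = mask.shape
    img = np.empty((h, w, 3), dtype=np.float64)
    soil_noise = rng.normal(0.0, 10.0, size=(h, w))
    soil_texture = ndimage.gaussian_filter(rng.normal(0.0, 30.0, size=(h, w)), sigma=6)
    img[:] = _SOIL_RGB + (soil_noise + soil_texture)[..., None]

    crop_noise = rng.normal(0.0, 12.0, size=(h, w))
    crop = _CROP_RGB + crop_noise[..., None]
    # canopy speckle: bright leaf highlights whose density tracks growth
    speckle = rng.random((h, w)) < 0.05 + 0.15 * params.growth_stage
    crop = np.where(speckle[..., None], crop + np.array([20.0, 45.0, 20.0]), crop)
    fg = mask.astype(bool)
    img[fg] = crop[fg]

    n_weeds = rng.poisson(params.weed_density * h * w / 1e4)
    lo, hi = params.weed_radius_range
    for _ in range(int(n_weeds)):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        r = rng.uniform(lo, hi)
        y0, y1 = max(0, int(cy - r) - 1), min(h, int(cy + r) + 2)
        x0, x1 = max(0, int(cx - r) - 1), min(w, int(cx + r) + 2)
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        patch = img[y0:y1, x0:x1]
        patch[disk] = _WEED_RGB + rng.normal(0.0, 8.0, size=3)

    if params.shade_fraction > 0:
        phi = rng.uniform(0.0, 2.0 * np.pi)
        yy, xx = np.mgrid[0:h, 0:w]
        proj = np.cos(phi) * xx + np.sin(phi) * yy
        proj = (proj - proj.min()) / max(proj.max() - proj.min(), 1e-9)
        # darken the shaded fraction, ramping from full shadow to none
        factor = np.where(
            proj < params.shade_fraction,
            0.45 + 0.55 * proj / max(params.shade_fraction, 1e-9),
            1.0,
        )
        img *= factor[..., None]

    return np.clip(img, 0.0, 255.0).astype(np.uint8)


def child_seed(seed: int, index: int) -> int:
    """Counter-based child seed: order-independent and reproducible."""
    return int(np.random.SeedSequence([int(seed), int(index)]).generate_state(1)[0] % (2**31))


def generate_dataset(n: int, params: FieldSceneParams, seed: int) -> list[FieldSample]:
    """Generate ``n`` independent scenes from deterministic child seeds."""
    if n < 1:
        raise ParameterError("n must be >= 1")
    return [generate_scene(params, child_seed(seed, i)) for i in range(n)]


def write_dataset(samples: list[FieldSample], directory) -> Path:
    """Write samples as images/ + masks/ PNGs and lines/ JSON; returns the manifest path.

    Masks are stored with foreground = 255 so they render as ordinary
    black-and-white PNGs.
    """
    from PIL import Image

    directory = Path(directory)
    for sub in ("images", "masks", "lines"):
        (directory / sub).mkdir(parents=True, exist_ok=True)
    entries = []
    for i, sample in enumerate(samples):
        stem = f"sample_{i:04d}"
        image_path = directory / "images" / f"{stem}.png"
        mask_path = directory / "masks" / f"{stem}.png"
        lines_path = directory / "lines" / f"{stem}.json"
        Image.fromarray(sample.image, mode="RGB").save(image_path)
        Image.fromarray((sample.mask * 255).astype(np.uint8), mode="L").save(mask_path)
        lines_path.write_text(
            json.dumps(
                {
                    "image_height": int(sample.mask.shape[0]),
                    "lines": [{"x0": line.x0, "x1": line.x1} for line in sample.gt_lines],
                },
                indent=1,
            )
        )
        entries.append({"image": f"images/{stem}.png", "mask": f"masks/{stem}.png", "lines": f"lines/{stem}.json"})
    manifest = directory / "manifest.json"
    manifest.write_text(json.dumps({"n": len(samples), "samples": entries}, indent=1))
    return manifest
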