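"""Configuration, dataset I/O and the end-to-end mask-to-navigation pipeline.

Datasets follow the images/ + masks/ folder convention (matching basenames,
8-bit PNGs, mask foreground >= 128); an optional lines/ folder carries
ground-truth centerlines as JSON.  :class:`PipelineConfig` bundles the
sub-configurations of every stage and round-trips through YAML.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import DatasetError
from .models import NetworkHandle, load_checkpoint, segment_image
from .navline import NavResult, RansacConfig, ScanConfig, fit_navigation
from .synthetic import FieldSample, FieldSceneParams, GroundTruthLine
from .training import TrainConfig

__all__ = ["PipelineConfig", "load_dataset", "run_end_to_end", "nav_result_to_dict"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage configurations plus dataset/checkpoint/output locations."""

    scan: ScanConfig = field(default_factory=ScanConfig)
    ransac: RansacConfig = field(default_factory=RansacConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    scene: FieldSceneParams = field(default_factory=FieldSceneParams)
    dataset_dir: str | None = None
    checkpoint: str | None = None
    output_dir: str = "outputs"
    seed: int = 0

    def validate(self) -> None:
        self.scan.validate()
        self.ransac.validate()
        self.train.validate()
        self.scene.validate()

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "scan" in d:
            d["scan"] = ScanConfig(**d["scan"])
        if "ransac" in d:
            d["ransac"] = RansacConfig(**d["ransac"])
        if "train" in d:
            train = dict(d["train"])
            if "decay_schedule" in train:
                train["decay_schedule"] = tuple(train["decay_schedule"])
            d["train"] = TrainConfig(**train)
        if "scene" in d:
            scene = dict(d["scene"])
            if "weed_radius_range" in scene:
                scene["weed_radius_range"] = tuple(scene["weed_radius_range"])
            d["scene"] = FieldSceneParams(**scene)
        return cls(**d)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data or {})


def _load_lines(path: Path) -> list[GroundTruthLine]:
    data = json.loads(path.read_text())
    return [GroundTruthLine(x0=e["x0"], x1=e["x1"]) for e in data["lines"]]


def load_dataset(directory) -> list[FieldSample]:
    """Load an images/ + masks/ folder into field samples.

    Masks are binarised at 128; image/mask pairs are matched by basename and
    unmatched files are skipped with a logged warning.  Raises
    :class:`DatasetError` when no pair matches.
    """
    from PIL import Image

    directory = Path(directory)
    images_dir, masks_dir, lines_dir = (directory / s for s in ("images", "masks", "lines"))
    if not images_dir.is_dir() or not masks_dir.is_dir():
        raise DatasetError(f"expected images/ and masks/ under {directory}")
    image_names = {p.stem: p for p in sorted(images_dir.iterdir()) if p.suffix.lower() in (".png", ".jpg", ".jpeg")}
    mask_names = {p.stem: p for p in sorted(masks_dir.iterdir()) if p.suffix.lower() == ".png"}
    common = sorted(set(image_names) & set(mask_names))
    skipped = sorted(set(image_names) ^ set(mask_names))
    for stem in skipped:
        logger.warning("unmatched dataset entry skipped: %s", stem)
    if not common:
        raise DatasetError(f"no matching image/mask basenames under {directory}")
    samples = []
    for stem in common:
        image = np.asarray(Image.open(image_names[stem]).convert("RGB"))
        mask = (np.asarray(Image.open(mask_names[stem]).convert("L")) >= 128).astype(np.uint8)
        lines_path = lines_dir / f"{stem}.json"
        gt_lines = _load_lines(lines_path) if lines_path.exists() else []
        samples.append(FieldSample(image=image, mask=mask, gt_lines=gt_lines))
    return samples


def nav_result_to_dict(result: NavResult, image_height: int) -> dict:
    """JSON-ready encoding of fitted lines (endpoints at y = 0 and y = H-1)."""

    def encode(line):
        (x0, _), (x1, _) = line.endpoints(image_height)
        return {
            "x0": x0,
            "x1": x1,
            "score": float(line.score),
            "inliers": int(line.m_t),
            "length": float(line.l),
        }

    return {
        "image_height": int(image_height),
        "row_lines": [encode(ln) for ln in result.row_lines],
        "navigation_line": encode(result.navigation_line) if result.navigation_line else None,
        "angles_vs_truth_deg": list(map(float, result.angles_vs_truth)),
    }


def run_end_to_end(
    image: np.ndarray,
    checkpoint,
    config: PipelineConfig | None = None,
    segmenter=None,
    truth: list[GroundTruthLine] | None = None,
) -> tuple[NavResult, np.ndarray]:
    """Segment an (H, W, 3) image and fit its navigation line.

    ``segmenter`` overrides the checkpointed network with any callable
    image -> probability map (used with oracle masks in validation).
    Returns the navigation result and a binary crop mask.
    """
    config = config or PipelineConfig()
    if segmenter is None:
        handle = checkpoint if isinstance(checkpoint, NetworkHandle) else load_checkpoint(checkpoint)
        prob = segment_image(handle, image)
    else:
        prob = np.asarray(segmenter(image), dtype=np.float64)
    mask = (prob >= 0.5).astype(np.uint8)
    rng = np.random.default_rng(config.seed)
    result = fit_navigation(mask, config.scan, config.ransac, rng, truth=truth)
    return result, mask


def overlay_lines(image: np.ndarray, result: NavResult) -> np.ndarray:
    """Render fitted row lines (red) and the navigation line (blue) on a copy."""
    from PIL import Image, ImageDraw

    img = Image.fromarray(np.asarray(image)).convert("RGB")
    draw = ImageDraw.Draw(img)
    h = img.height
    for line in result.row_lines:
        (x0, y0), (x1, y1) = line.endpoints(h)
        draw.line([(x0, y0), (x1, y1)], fill=(220, 40, 40), width=2)
    if result.navigation_line is not None:
        (x0, y0), (x1, y1) = result.navigation_line.endpoints(h)
        draw.line([(x0, y0), (x1, y1)], fill=(40, 80, 230), width=3)
    return np.asarray(img)
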