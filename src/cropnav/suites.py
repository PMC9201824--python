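"""Reference evaluation suites run by the test suite and the results script.

Each suite generates its inputs with the synthetic scene generator, runs the
relevant pipeline stage end to end, and returns plain dictionaries of
metrics.  All randomness flows from the single seed each function receives.
"""

from __future__ import annotations

import numpy as np

from . import models, navline, synthetic, training

__all__ = [
    "sample_scene_params",
    "line_fitting_suite",
    "segmentation_training_suite",
    "parameter_counts_m",
]


def sample_scene_params(
    base: synthetic.FieldSceneParams,
    rng: np.random.Generator,
    n_rows_choices: tuple[int, ...] = (3, 4, 5),
    max_angle_deg: float = 5.0,
) -> synthetic.FieldSceneParams:
    """Draw per-scene variability: row count and a near-vertical row angle."""
    return base.with_(
        n_rows=int(rng.choice(n_rows_choices)),
        row_angle=float(rng.uniform(-max_angle_deg, max_angle_deg)),
    )


def line_fitting_suite(
    seed: int,
    n_images: int = 100,
    image_size: int = 512,
    jaggedness: float = 2.0,
    spurious_fraction: float = 0.10,
    scan: navline.ScanConfig = navline.ScanConfig(),
    ransac: navline.RansacConfig = navline.RansacConfig(),
) -> dict:
    """Navigation-line recovery on a seeded suite of synthetic masks.

    Generates ``n_images`` scenes with 3–5 near-vertical rows and the given
    boundary jaggedness, injects uniformly scattered spurious feature points
    (emulating weed specks surviving segmentation) at ``spurious_fraction``
    of the point cloud, runs scan-line extraction plus the improved RANSAC,
    and scores every image's navigation line against its nearest true
    centerline.  Returns per-image angles, their maximum, and the percentage
    of images within the 7-degree correctness tolerance.
    """
    base = synthetic.FieldSceneParams(
        image_height=image_size,
        image_width=image_size,
        row_spacing=int(round(image_size * 110 / 512)),
        row_width=max(4, int(round(image_size * 30 / 512))),
        jaggedness=jaggedness,
        weed_density=0.0,
        shade_fraction=0.0,
    )
    master = np.random.default_rng(np.random.SeedSequence(seed))
    angles: list[float] = []
    found = 0
    for i in range(n_images):
        scene_seed = synthetic.child_seed(seed, i)
        params = sample_scene_params(base, np.random.default_rng(scene_seed))
        sample = synthetic.generate_scene(params, scene_seed)
        points = navline.extract_feature_points(sample.mask, scan)
        if spurious_fraction > 0:
            points = navline.inject_spurious_points(
                points, spurious_fraction, master, sample.mask.shape
            )
        result = navline.fit_navigation(
            sample.mask, scan, ransac, master, truth=sample.gt_lines, points=points
        )
        if result.navigation_line is None:
            angles.append(float("inf"))
            continue
        found += 1
        h = sample.mask.shape[0]
        match = min(
            sample.gt_lines,
            key=lambda t: abs(t.abscissa_at((h - 1) / 2.0, h) - result.navigation_line.x_mid),
        )
        angles.append(navline.angle_between(result.navigation_line, match, h))
    finite = [a for a in angles if np.isfinite(a)]
    correct = sum(a <= navline.ANGLE_TOLERANCE_DEG for a in finite)
    return {
        "n_images": n_images,
        "n_detected": found,
        "angles_deg": angles,
        "max_angle_deg": float(max(finite)) if finite else float("inf"),
        "accuracy_pct": 100.0 * correct / n_images,
    }


def segmentation_training_suite(
    seed: int,
    n_train: int = 200,
    n_val: int = 20,
    image_size: int = 128,
    epochs: int = 10,
    width_multiplier: float = 0.5,
) -> dict:
    """Scaled-down segmentation training run on synthetic scenes.

    Trains the reduced-width improved network for a short schedule with the
    standard hyperparameters (Adam, lr 1e-4, batch 8, BCE + Dice with
    smooth 0.1, augmentation probability 0.5) and reports the held-out mean
    crop-class IoU at probability threshold 0.5.
    """
    base = synthetic.FieldSceneParams(
        image_height=image_size,
        image_width=image_size,
        n_rows=3,
        row_spacing=int(round(image_size * 110 / 512)) + 8,
        row_width=max(4, int(round(image_size * 30 / 512)) + 4),
        jaggedness=1.0,
        weed_density=0.5,
        shade_fraction=0.3,
    )
    data_seed = synthetic.child_seed(seed, 1_000_003)
    samples = []
    for i in range(n_train + n_val):
        scene_seed = synthetic.child_seed(data_seed, i)
        params = sample_scene_params(base, np.random.default_rng(scene_seed))
        samples.append(synthetic.generate_scene(params, scene_seed))
    train_set, val_set = samples[:n_train], samples[n_train:]

    spec = models.ArchitectureSpec.improved(width_multiplier=width_multiplier)
    net = models.build_improved_enet(spec, seed=synthetic.child_seed(seed, 7))
    config = training.TrainConfig(
        epochs=epochs,
        batch_size=8,
        learning_rate=1e-4,
        augment_prob=0.5,
        input_size=image_size,
        seed=synthetic.child_seed(seed, 11),
    )
    report = training.train(net, train_set, val_set, config)
    return {
        "n_train": n_train,
        "n_val": n_val,
        "epochs": epochs,
        "parameter_count": net.parameter_count,
        "loss_curve": report.loss_curve,
        "val_iou_curve": report.val_iou_curve,
        "mean_val_iou": float(report.final_metrics.mean_iou),
        "detection_accuracy_pct": float(report.final_metrics.detection_accuracy_pct),
    }


def parameter_counts_m() -> dict:
    """Trainable-parameter counts (in millions) of both architectures at default widths."""
    improved = models.build_improved_enet(models.ArchitectureSpec.improved())
    classic = models.build_classic_enet(models.ArchitectureSpec.classic())
    return {
        "improved_m": improved.parameter_count / 1e6,
        "classic_m": classic.parameter_count / 1e6,
    }
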