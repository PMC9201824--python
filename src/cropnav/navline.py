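"""Crop-row centerline and navigation-line extraction from binary masks.

The segmented mask is scanned with horizontal lines every ``h`` pixels
(default 8).  Each maximal foreground run contributes one feature point at
the midpoint of its two edge intersections (``per_run`` mode); the literal
all-intersections mean (one point per scan line) is available as ``global``
mode.  Candidate lines are then fitted by a RANSAC variant whose two seed
points must be widely separated along the row direction (so both ends of a
row constrain the model) and whose candidates are ranked by the inlier
density score  m_t / (l + p)  — inlier count over inlier span plus a
regulariser p (default 15).  The best candidate's inlier set is refined by
orthogonal least squares.  Rows are extracted sequentially by removing each
fitted line's inliers; the navigation line is the row line closest to the
image centre.  Against ground truth a detection is correct when the acute
angle between fitted and true line is at most 7 degrees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import FitError, ParameterError, SamplingExhausted, ValidationError
from .synthetic import GroundTruthLine

__all__ = [
    "FeaturePoint",
    "ScanConfig",
    "CandidateLine",
    "FittedLine",
    "RansacConfig",
    "NavResult",
    "extract_feature_points",
    "points_array",
    "inject_spurious_points",
    "sample_candidate_pair",
    "line_inliers",
    "score_line",
    "ransac_fit_single",
    "fit_all_rows",
    "select_navigation_line",
    "angle_between",
    "line_accuracy",
    "fit_navigation",
]

logger = logging.getLogger(__name__)

#: A navigation line within this acute angle of truth counts as correct.
ANGLE_TOLERANCE_DEG = 7.0


@dataclass(frozen=True)
class FeaturePoint:
    """A scan-line feature point: x is the run-centre abscissa, y = h*N."""

    x: float
    y: float


@dataclass(frozen=True)
class ScanConfig:
    """Feature-point extraction settings.

    ``h`` is the scan-line interval in pixels.  ``mode`` selects one point
    per foreground run (``per_run``) or the literal one-point-per-scan-line
    mean over all edge intersections (``global``).  ``orientation`` is the
    scan direction; ``horizontal`` scans image rows, which suits the
    near-vertical crop rows of overhead imagery.
    """

    h: int = 8
    mode: str = "per_run"
    orientation: str = "horizontal"

    def validate(self) -> None:
        if self.h < 1:
            raise ParameterError("scan interval h must be >= 1")
        if self.mode not in ("per_run", "global"):
            raise ParameterError("mode must be 'per_run' or 'global'")
        if self.orientation not in ("horizontal", "vertical"):
            raise ParameterError("orientation must be 'horizontal' or 'vertical'")


@dataclass(frozen=True)
class RansacConfig:
    """Improved-RANSAC settings.

    ``T`` is the coordinate separation threshold for the two seed points;
    when None it defaults to one third of the image extent along
    ``separation_axis``.  The axis is ``y`` for near-vertical rows (wide
    separation along the row) and ``x`` for the literal abscissa form.
    ``dist_threshold`` is the inlier point-to-line distance and ``p`` the
    score regulariser of  score = m_t / (l + p).
    """

    T: float | None = None
    separation_axis: str = "y"
    dist_threshold: float = 4.0
    p: float = 15.0
    max_iterations: int = 500
    early_stop_score: float | None = None
    min_points_per_row: int = 5
    min_score: float | None = 0.05
    max_pair_retries: int = 100
    exhaustive: bool = False

    def validate(self) -> None:
        if self.T is not None and self.T <= 0:
            raise ParameterError("T must be positive")
        if self.separation_axis not in ("x", "y"):
            raise ParameterError("separation_axis must be 'x' or 'y'")
        if self.dist_threshold <= 0:
            raise ParameterError("dist_threshold must be positive")
        if self.T is not None and self.dist_threshold >= self.T:
            raise ParameterError("dist_threshold must be smaller than T")
        if self.p <= 0:
            raise ParameterError("score regulariser p must be positive")
        if self.max_iterations < 1:
            raise ParameterError("max_iterations must be >= 1")
        if self.min_points_per_row < 2:
            raise ParameterError("min_points_per_row must be >= 2")
        if self.min_score is not None and self.min_score < 0:
            raise ParameterError("min_score must be non-negative")


@dataclass(frozen=True)
class CandidateLine:
    """A line hypothesis through two sampled feature points."""

    p1: FeaturePoint
    p2: FeaturePoint
    direction: np.ndarray  # unit 2-vector (dx, dy)

    @property
    def anchor(self) -> np.ndarray:
        return np.array([self.p1.x, self.p1.y])


@dataclass
class FittedLine:
    """A fitted row centerline with its consensus set and density score."""

    point: np.ndarray  # a point on the line (x, y)
    direction: np.ndarray  # unit direction, oriented with dy >= 0
    inliers: np.ndarray  # (k, 2) inlier coordinates
    m_t: int  # inlier count
    l: float  # span of inlier projections onto the line, pixels
    score: float  # m_t / (l + p)
    x_mid: float = float("nan")  # abscissa at image mid-height
    sample_score: float = float("nan")  # best pre-refit candidate score

    def abscissa_at(self, y: float) -> float:
        dx, dy = self.direction
        if abs(dy) < 1e-12:
            return float(self.point[0])
        t = (y - self.point[1]) / dy
        return float(self.point[0] + t * dx)

    def endpoints(self, image_height: int) -> tuple[tuple[float, float], tuple[float, float]]:
        return (self.abscissa_at(0.0), 0.0), (
            self.abscissa_at(image_height - 1.0),
            image_height - 1.0,
        )


@dataclass
class NavResult:
    """Fitted row lines, the selected navigation line and per-row angular errors."""

    row_lines: list[FittedLine] = field(default_factory=list)
    navigation_line: FittedLine | None = None
    angles_vs_truth: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Feature-point extraction (scan lines every h pixels)
# ---------------------------------------------------------------------------


def _scan_rows(mask: np.ndarray, h: int, mode: str) -> list[FeaturePoint]:
    points: list[FeaturePoint] = []
    height = mask.shape[0]
    for y in range(0, height, h):
        row = mask[y]
        edges = np.diff(np.concatenate(([0], row, [0])).astype(np.int8))
        starts = np.flatnonzero(edges == 1)
        ends = np.flatnonzero(edges == -1) - 1  # last foreground pixel of each run
        if starts.size == 0:
            continue
        if mode == "per_run":
            for s, e in zip(starts, ends):
                points.append(FeaturePoint(x=(s + e) / 2.0, y=float(y)))
        else:  # one point per scan line: mean of all edge intersections
            points.append(FeaturePoint(x=float(np.concatenate([starts, ends]).mean()), y=float(y)))
    return points


def extract_feature_points(mask: np.ndarray, config: ScanConfig = ScanConfig()) -> list[FeaturePoint]:
    """Feature points of a binary crop mask along equally spaced scan lines."""
    config.validate()
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValidationError(f"mask must be 2-D, got shape {mask.shape}")
    if not np.isin(mask, (0, 1)).all():
        raise ValidationError("mask must be binary (0/1)")
    if config.orientation == "horizontal":
        return _scan_rows(mask, config.h, config.mode)
    transposed = _scan_rows(mask.T, config.h, config.mode)
    return [FeaturePoint(x=p.y, y=p.x) for p in transposed]


def points_array(points) -> np.ndarray:
    """(n, 2) float array of (x, y) coordinates from points in any accepted form."""
    if isinstance(points, np.ndarray):
        return points.reshape(-1, 2).astype(np.float64)
    return np.array([(p.x, p.y) for p in points], dtype=np.float64).reshape(-1, 2)


def inject_spurious_points(
    points, fraction: float, rng: np.random.Generator, image_shape: tuple[int, int]
) -> list[FeaturePoint]:
    """Add uniform clutter so that it makes up ``fraction`` of the returned set.

    Emulates spurious feature points caused by weed specks surviving
    segmentation; used by the robustness suites.
    """
    if not 0.0 <= fraction < 1.0:
        raise ParameterError("fraction must lie in [0, 1)")
    pts = list(points)
    n_extra = int(round(len(pts) * fraction / (1.0 - fraction)))
    h, w = image_shape
    xs = rng.uniform(0, w - 1, size=n_extra)
    ys = rng.uniform(0, h - 1, size=n_extra)
    pts.extend(FeaturePoint(x=float(x), y=float(y)) for x, y in zip(xs, ys))
    return pts


# ---------------------------------------------------------------------------
# Improved RANSAC
# ---------------------------------------------------------------------------


def _unit_direction(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    v = q - p
    norm = np.linalg.norm(v)
    if norm < 1e-12:
        raise FitError("degenerate candidate: coincident points")
    v = v / norm
    if v[1] < 0 or (v[1] == 0 and v[0] < 0):
        v = -v  # canonical orientation: pointing down the image
    return v


def sample_candidate_pair(points, T: float, rng: np.random.Generator, axis: str = "y", max_retries: int = 100) -> CandidateLine:
    """Draw two feature points separated by more than ``T`` along ``axis``.

    Rejection sampling with a bounded retry budget; raises
    :class:`SamplingExhausted` when no qualifying pair turns up, at which
    point callers fall back to unconstrained sampling.
    """
    pts = points_array(points)
    if len(pts) < 2:
        raise FitError("need at least two feature points")
    col = 1 if axis == "y" else 0
    for _ in range(max_retries):
        i, j = rng.choice(len(pts), size=2, replace=False)
        if abs(pts[i, col] - pts[j, col]) > T:
            return CandidateLine(
                p1=FeaturePoint(*pts[i]),
                p2=FeaturePoint(*pts[j]),
                direction=_unit_direction(pts[i], pts[j]),
            )
    raise SamplingExhausted(
        f"no point pair separated by more than T={T:.1f} along {axis!r} "
        f"within {max_retries} draws"
    )


def _distances(anchor: np.ndarray, direction: np.ndarray, pts: np.ndarray) -> np.ndarray:
    rel = pts - anchor
    return np.abs(rel[:, 0] * direction[1] - rel[:, 1] * direction[0])


def line_inliers(line: CandidateLine, points, dist_threshold: float) -> np.ndarray:
    """Points within perpendicular distance ``dist_threshold`` (closed bound)."""
    pts = points_array(points)
    d = _distances(line.anchor, np.asarray(line.direction, dtype=np.float64), pts)
    return pts[d <= dist_threshold]


def score_line(m_t: int, l: float, p: float = 15.0) -> float:
    """Inlier-density score  m_t / (l + p);  higher ranks better."""
    if p <= 0:
        raise ParameterError("score regulariser p must be positive")
    if m_t < 0 or l < 0:
        raise ParameterError("m_t and l must be non-negative")
    return m_t / (l + p)


def _span(proj: np.ndarray) -> float:
    return float(proj.max() - proj.min()) if proj.size else 0.0


def _tls_refit(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal least-squares line through a point set: centroid + principal axis."""
    centroid = pts.mean(axis=0)
    centred = pts - centroid
    cov = centred.T @ centred
    eigvals, eigvecs = np.linalg.eigh(cov)
    direction = eigvecs[:, int(np.argmax(eigvals))]
    if direction[1] < 0 or (direction[1] == 0 and direction[0] < 0):
        direction = -direction
    return centroid, direction


def _candidate_pairs(pts: np.ndarray, T: float, col: int):
    n = len(pts)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n) if abs(pts[i, col] - pts[j, col]) > T]
    if not pairs:
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        logger.warning("no pair satisfies the separation constraint; enumerating all pairs")
    return pairs


def _default_T(cfg: RansacConfig, pts: np.ndarray, image_shape) -> float:
    if cfg.T is not None:
        return cfg.T
    col = 1 if cfg.separation_axis == "y" else 0
    if image_shape is not None:
        extent = image_shape[0] if cfg.separation_axis == "y" else image_shape[1]
    else:
        extent = pts[:, col].max() - pts[:, col].min()
    return max(float(extent) / 3.0, 1.0)


def ransac_fit_single(
    points,
    config: RansacConfig = RansacConfig(),
    rng: np.random.Generator | None = None,
    image_shape: tuple[int, int] | None = None,
) -> FittedLine:
    """Fit one line: constrained sampling, density scoring, orthogonal refit.

    Keeps the best-scoring candidate over ``max_iterations`` draws (or an
    exhaustive deterministic sweep of all qualifying pairs when
    ``config.exhaustive``), then re-estimates the line from the winning
    consensus set by orthogonal least squares and recomputes its inliers,
    span and score.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(0)
    pts = points_array(points)
    if len(pts) < 2:
        raise FitError("need at least two feature points to fit a line")
    T = _default_T(config, pts, image_shape)
    col = 1 if config.separation_axis == "y" else 0

    best_score = -np.inf
    best_inlier_mask = None
    fallback_warned = False

    if config.exhaustive:
        candidates = _candidate_pairs(pts, T, col)
    else:
        candidates = range(config.max_iterations)

    for item in candidates:
        if config.exhaustive:
            i, j = item
            try:
                direction = _unit_direction(pts[i], pts[j])
            except FitError:
                continue
            anchor = pts[i]
        else:
            try:
                cand = sample_candidate_pair(pts, T, rng, axis=config.separation_axis, max_retries=config.max_pair_retries)
            except SamplingExhausted:
                if not fallback_warned:
                    logger.warning("separation constraint unsatisfiable; falling back to unconstrained sampling")
                    fallback_warned = True
                i, j = rng.choice(len(pts), size=2, replace=False)
                try:
                    direction = _unit_direction(pts[i], pts[j])
                except FitError:
                    continue
                anchor = pts[i]
            else:
                anchor, direction = cand.anchor, cand.direction
        d = _distances(anchor, direction, pts)
        mask = d <= config.dist_threshold
        m_t = int(mask.sum())
        if m_t < 2:
            continue
        proj = (pts[mask] - anchor) @ direction
        s = score_line(m_t, _span(proj), config.p)
        if s > best_score:
            best_score = s
            best_inlier_mask = mask
        if config.early_stop_score is not None and best_score >= config.early_stop_score:
            break

    if best_inlier_mask is None:
        raise FitError("no candidate line gathered a consensus set")

    centroid, direction = _tls_refit(pts[best_inlier_mask])
    d = _distances(centroid, direction, pts)
    mask = d <= config.dist_threshold
    inliers = pts[mask]
    proj = (inliers - centroid) @ direction
    l = _span(proj)
    fitted = FittedLine(
        point=centroid,
        direction=direction,
        inliers=inliers,
        m_t=int(mask.sum()),
        l=l,
        score=score_line(int(mask.sum()), l, config.p),
        sample_score=float(best_score),
    )
    fitted._inlier_mask = mask  # consumed by fit_all_rows for removal
    height = image_shape[0] if image_shape is not None else (pts[:, 1].max() + 1)
    fitted.x_mid = fitted.abscissa_at((height - 1) / 2.0)
    return fitted


def fit_all_rows(
    points,
    config: RansacConfig = RansacConfig(),
    rng: np.random.Generator | None = None,
    image_shape: tuple[int, int] | None = None,
) -> list[FittedLine]:
    """Extract every row centerline by sequential consensus removal.

    Repeatedly fits the best remaining line and removes its inliers until
    fewer than ``min_points_per_row`` points remain, a fit's consensus falls
    below that floor, or its density score drops under ``min_score`` (the
    point at which remaining structure is indistinguishable from clutter).
    Lines are ordered left to right by their abscissa at image mid-height.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(0)
    pts = points_array(points)
    lines: list[FittedLine] = []
    while len(pts) >= config.min_points_per_row:
        try:
            fitted = ransac_fit_single(pts, config, rng, image_shape=image_shape)
        except (FitError, SamplingExhausted):
            break
        if fitted.m_t < config.min_points_per_row:
            break
        if config.min_score is not None and fitted.score < config.min_score:
            break  # inlier density below a plausible crop row; rest is clutter
        lines.append(fitted)
        pts = pts[~fitted._inlier_mask]
    lines.sort(key=lambda ln: ln.x_mid)
    return lines


def select_navigation_line(lines: list[FittedLine], image_width: int) -> FittedLine:
    """The row line nearest the image centre at mid-height; ties favour score."""
    if not lines:
        raise FitError("cannot select a navigation line from an empty list")
    centre = (image_width - 1) / 2.0
    return min(lines, key=lambda ln: (abs(ln.x_mid - centre), -ln.score))


def _direction_of(obj, image_height: int | None) -> np.ndarray:
    if isinstance(obj, FittedLine):
        return np.asarray(obj.direction, dtype=np.float64)
    if isinstance(obj, GroundTruthLine):
        if image_height is None:
            raise ParameterError("image_height is required to orient a GroundTruthLine")
        return obj.direction(image_height)
    if isinstance(obj, CandidateLine):
        return np.asarray(obj.direction, dtype=np.float64)
    raise ParameterError(f"cannot extract a direction from {type(obj).__name__}")


def angle_between(a, b, image_height: int | None = None) -> float:
    """Acute angle in degrees between two lines' directions, in [0, 90]."""
    va = _direction_of(a, image_height)
    vb = _direction_of(b, image_height)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na < 1e-12 or nb < 1e-12:
        raise FitError("zero-length direction vector")
    cosang = abs(float(va @ vb) / (na * nb))
    return float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))


def _nearest_truth(nav: FittedLine, truth: list[GroundTruthLine], image_height: int) -> GroundTruthLine:
    y_mid = (image_height - 1) / 2.0
    return min(truth, key=lambda t: abs(t.abscissa_at(y_mid, image_height) - nav.x_mid))


def line_accuracy(
    pred: list[NavResult],
    truth: list[list[GroundTruthLine]],
    image_height: int,
    tolerance: float = ANGLE_TOLERANCE_DEG,
) -> float:
    """Percentage of images whose navigation line is within ``tolerance`` degrees
    of its nearest ground-truth centerline; a missing line counts as incorrect."""
    if len(pred) != len(truth):
        raise ValidationError(f"prediction/truth length mismatch: {len(pred)} vs {len(truth)}")
    if not pred:
        raise ValidationError("line_accuracy requires a non-empty suite")
    correct = 0
    for result, gt in zip(pred, truth):
        if result.navigation_line is None or not gt:
            continue
        match = _nearest_truth(result.navigation_line, gt, image_height)
        if angle_between(result.navigation_line, match, image_height) <= tolerance:
            correct += 1
    return 100.0 * correct / len(pred)


def fit_navigation(
    mask: np.ndarray,
    scan: ScanConfig = ScanConfig(),
    ransac: RansacConfig = RansacConfig(),
    rng: np.random.Generator | None = None,
    truth: list[GroundTruthLine] | None = None,
    points=None,
) -> NavResult:
    """Full mask-to-navigation-line pipeline; optionally scores against truth.

    ``points`` overrides feature extraction (used to inject clutter in
    robustness studies); otherwise points come from ``extract_feature_points``.
    """
    mask = np.asarray(mask)
    if points is None:
        points = extract_feature_points(mask, scan)
    lines = fit_all_rows(points, ransac, rng, image_shape=mask.shape)
    result = NavResult(row_lines=lines)
    if lines:
        result.navigation_line = select_navigation_line(lines, mask.shape[1])
    if truth:
        h = mask.shape[0]
        result.angles_vs_truth = [
            angle_between(ln, _nearest_truth(ln, truth, h), h) for ln in lines
        ]
    return result
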