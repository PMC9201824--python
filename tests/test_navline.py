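"""Feature extraction, RANSAC fitting and navigation-line selection tests."""

import numpy as np
import pytest

from cropnav import navline, synthetic
from cropnav.errors import FitError, ParameterError, SamplingExhausted, ValidationError
from cropnav.navline import (
    CandidateLine,
    FeaturePoint,
    FittedLine,
    NavResult,
    RansacConfig,
    ScanConfig,
    angle_between,
    extract_feature_points,
    fit_all_rows,
    line_accuracy,
    line_inliers,
    points_array,
    ransac_fit_single,
    sample_candidate_pair,
    score_line,
    select_navigation_line,
)


def _line_from_angle(deg_from_vertical: float) -> FittedLine:
    rad = np.radians(deg_from_vertical)
    return FittedLine(
        point=np.zeros(2),
        direction=np.array([np.sin(rad), np.cos(rad)]),
        inliers=np.empty((0, 2)),
        m_t=0,
        l=0.0,
        score=0.0,
    )


class TestExtraction:
    def test_single_run_midpoint(self):
        mask = np.zeros((16, 40), dtype=np.uint8)
        mask[8, 10:21] = 1  # run spanning x in [10, 20]
        pts = extract_feature_points(mask, ScanConfig(h=8))
        assert pts == [FeaturePoint(x=15.0, y=8.0)]

    def test_empty_mask_gives_no_points(self):
        assert extract_feature_points(np.zeros((32, 32), dtype=np.uint8)) == []

    def test_three_bands_one_point_per_run(self, clean_params):
        sample = synthetic.generate_scene(clean_params, seed=0)
        pts = extract_feature_points(sample.mask, ScanConfig(h=8, mode="per_run"))
        n_lines = len(range(0, 512, 8))
        assert len(pts) == 3 * n_lines
        centres = sorted({line.x0 for line in sample.gt_lines})
        for y in range(0, 512, 8):
            xs = sorted(p.x for p in pts if p.y == y)
            assert xs == pytest.approx(centres, abs=0.5)

    def test_global_mode_emits_one_point_per_scan_line(self, clean_params):
        sample = synthetic.generate_scene(clean_params, seed=0)
        pts = extract_feature_points(sample.mask, ScanConfig(h=8, mode="global"))
        assert len(pts) == len(range(0, 512, 8))
        # symmetric bands: the all-intersections mean is the image centre
        assert all(abs(p.x - 255.5) < 1.0 for p in pts)

    def test_vertical_orientation_swaps_axes(self):
        mask = np.zeros((40, 16), dtype=np.uint8)
        mask[10:21, 8] = 1  # vertical run at x=8, y in [10, 20]
        pts = extract_feature_points(mask, ScanConfig(h=8, orientation="vertical"))
        assert pts == [FeaturePoint(x=8.0, y=15.0)]

    def test_non_binary_mask_rejected(self):
        with pytest.raises(ValidationError):
            extract_feature_points(np.full((8, 8), 3))


class TestSampling:
    def test_widely_separated_pair_accepted_first_try(self, rng):
        pts = [FeaturePoint(0.0, 0.0), FeaturePoint(0.0, 100.0)]
        cand = sample_candidate_pair(pts, T=50.0, rng=rng, axis="y")
        assert {cand.p1.y, cand.p2.y} == {0.0, 100.0}
        np.testing.assert_allclose(cand.direction, [0.0, 1.0])

    def test_identical_points_exhaust_sampling(self, rng):
        pts = [FeaturePoint(5.0, 5.0)] * 6
        with pytest.raises(SamplingExhausted):
            sample_candidate_pair(pts, T=1.0, rng=rng, max_retries=20)

    def test_accepted_pairs_always_satisfy_the_constraint(self, rng):
        pts = [FeaturePoint(float(x), float(y)) for x, y in rng.uniform(0, 200, size=(40, 2))]
        for _ in range(1000):
            cand = sample_candidate_pair(pts, T=60.0, rng=rng, axis="y")
            assert abs(cand.p1.y - cand.p2.y) > 60.0


class TestInliers:
    def test_defining_points_are_inliers_and_boundary_is_closed(self, rng):
        p1, p2 = FeaturePoint(0.0, 0.0), FeaturePoint(0.0, 50.0)
        cand = CandidateLine(p1=p1, p2=p2, direction=np.array([0.0, 1.0]))
        pts = [p1, p2, FeaturePoint(4.0, 25.0), FeaturePoint(4.0001, 30.0)]
        inl = line_inliers(cand, pts, dist_threshold=4.0)
        assert len(inl) == 3  # the exactly-at-threshold point is included
        assert [0.0, 0.0] in inl.tolist() and [4.0, 25.0] in inl.tolist()

    def test_matches_brute_force_distances(self, rng):
        pts = rng.uniform(0, 100, size=(60, 2))
        a, b = pts[0], pts[1]
        d = (b - a) / np.linalg.norm(b - a)
        cand = CandidateLine(FeaturePoint(*a), FeaturePoint(*b), d)
        got = line_inliers(cand, pts, dist_threshold=7.0)
        expected = [
            p
            for p in pts
            if np.linalg.norm((p - a) - ((p - a) @ d) * d) <= 7.0
        ]
        np.testing.assert_allclose(got, np.array(expected))


class TestScore:
    def test_direct_substitution(self):
        assert score_line(30, 45.0, 15.0) == pytest.approx(0.5)
        assert score_line(0, 123.0) == 0.0

    def test_strictly_decreasing_in_length(self):
        scores = [score_line(20, l) for l in (0.0, 10.0, 100.0, 1000.0)]
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_invalid_regulariser_rejected(self):
        with pytest.raises(ParameterError):
            score_line(10, 5.0, 0.0)


class TestRansacSingle:
    def test_collinear_points_recovered_exactly(self, rng):
        ys = np.linspace(0, 90, 10)
        pts = np.stack([12.0 + 0.2 * ys, ys], axis=1)
        fit = ransac_fit_single(pts, RansacConfig(T=30.0, dist_threshold=1.0), rng)
        assert fit.m_t == 10
        d = pts - fit.point
        dists = np.abs(d[:, 0] * fit.direction[1] - d[:, 1] * fit.direction[0])
        assert dists.max() < 1e-9

    def test_exhaustive_sweep_matches_brute_force_oracle(self):
        """Independent pair enumeration reproduces the best density score."""
        cfg = RansacConfig(T=25.0, dist_threshold=3.0, exhaustive=True)
        for seed in range(25):
            rng = np.random.default_rng(seed)
            pts = rng.uniform(0, 80, size=(rng.integers(5, 13), 2))
            best = -np.inf
            for i in range(len(pts)):
                for j in range(i + 1, len(pts)):
                    if abs(pts[i, 1] - pts[j, 1]) <= 25.0:
                        continue
                    d = pts[j] - pts[i]
                    d = d / np.linalg.norm(d)
                    rel = pts - pts[i]
                    dist = np.abs(rel[:, 0] * d[1] - rel[:, 1] * d[0])
                    sel = dist <= 3.0
                    if sel.sum() < 2:
                        continue
                    proj = rel[sel] @ d
                    best = max(best, sel.sum() / (proj.max() - proj.min() + 15.0))
            if best == -np.inf:
                continue
            fit = ransac_fit_single(pts, cfg, np.random.default_rng(0))
            assert fit.sample_score == pytest.approx(best, abs=1e-12)

    def test_outlier_contamination_monte_carlo(self):
        """80% on-line / 20% uniform outliers: angle within 1 degree in >= 95/100 runs."""
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            ys = np.linspace(0, 500, 24)
            on_line = np.stack([100.0 + 0.05 * ys + rng.normal(0, 0.5, ys.size), ys], axis=1)
            outliers = rng.uniform(0, 500, size=(6, 2))
            pts = np.vstack([on_line, outliers])
            fit = ransac_fit_single(pts, RansacConfig(max_iterations=200), rng, image_shape=(512, 512))
            truth = np.array([0.05, 1.0])
            truth /= np.linalg.norm(truth)
            ang = np.degrees(np.arccos(np.clip(abs(fit.direction @ truth), 0, 1)))
            hits += ang < 1.0
        assert hits >= 95

    def test_too_few_points_raise(self, rng):
        with pytest.raises(FitError):
            ransac_fit_single(np.array([[1.0, 2.0]]), RansacConfig(), rng)

    def test_refit_keeps_all_inliers_on_collinear_data(self, rng):
        ys = np.linspace(0, 200, 15)
        pts = np.stack([50.0 + 0.1 * ys, ys], axis=1)
        cfg = RansacConfig(T=60.0, dist_threshold=2.0)
        fit = ransac_fit_single(pts, cfg, rng)
        assert fit.m_t == len(pts)  # the orthogonal refit loses no inliers


class TestFitAllRows:
    def test_three_clean_bands_give_three_centre_lines(self, clean_params, rng):
        sample = synthetic.generate_scene(clean_params, seed=0)
        pts = extract_feature_points(sample.mask)
        lines = fit_all_rows(pts, RansacConfig(), rng, image_shape=sample.mask.shape)
        assert len(lines) == 3
        expected = sorted(line.x0 for line in sample.gt_lines)
        assert [ln.x_mid for ln in lines] == pytest.approx(expected, abs=1.0)

    def test_single_row(self, clean_params, rng):
        sample = synthetic.generate_scene(clean_params.with_(n_rows=1), seed=0)
        lines = fit_all_rows(
            extract_feature_points(sample.mask), RansacConfig(), rng, image_shape=sample.mask.shape
        )
        assert len(lines) == 1

    def test_pure_noise_yields_no_confident_rows(self, rng):
        pts = rng.uniform(0, 512, size=(40, 2))
        lines = fit_all_rows(pts, RansacConfig(), rng, image_shape=(512, 512))
        assert all(ln.score >= 0.05 for ln in lines)
        assert len(lines) <= 1  # at most an accidental alignment survives


class TestSelection:
    def test_single_line_selected(self):
        ln = _line_from_angle(0.0)
        ln.x_mid = 10.0
        assert select_navigation_line([ln], image_width=512) is ln

    def test_middle_of_three_symmetric_lines(self):
        lines = []
        for x in (100.0, 255.5, 411.0):
            ln = _line_from_angle(0.0)
            ln.x_mid = x
            lines.append(ln)
        assert select_navigation_line(lines, image_width=512).x_mid == 255.5

    def test_tie_broken_by_score(self):
        a, b = _line_from_angle(0.0), _line_from_angle(0.0)
        a.x_mid, a.score = 200.0, 0.1
        b.x_mid, b.score = 311.0, 0.9
        assert select_navigation_line([a, b], image_width=512) is b

    def test_empty_selection_raises(self):
        with pytest.raises(FitError):
            select_navigation_line([], image_width=512)


class TestAngles:
    def test_identical_and_perpendicular(self):
        a = _line_from_angle(5.0)
        assert angle_between(a, _line_from_angle(5.0)) == pytest.approx(0.0, abs=1e-9)
        assert angle_between(_line_from_angle(0.0), _line_from_angle(90.0)) == pytest.approx(90.0)

    def test_ten_vs_three_degrees_is_seven(self):
        assert angle_between(_line_from_angle(10.0), _line_from_angle(3.0)) == pytest.approx(7.0, abs=1e-9)

    def test_ground_truth_lines_need_image_height(self):
        gt = synthetic.GroundTruthLine(x0=10.0, x1=10.0)
        assert angle_between(_line_from_angle(0.0), gt, image_height=512) == pytest.approx(0.0)
        with pytest.raises(ParameterError):
            angle_between(_line_from_angle(0.0), gt)


class TestLineAccuracy:
    def _nav(self, deg, x_mid=255.5):
        ln = _line_from_angle(deg)
        ln.x_mid = x_mid
        return NavResult(row_lines=[ln], navigation_line=ln)

    def test_exact_recoveries_and_misses(self):
        truth = [[synthetic.GroundTruthLine(255.5, 255.5)]] * 4
        perfect = [self._nav(0.0)] * 4
        assert line_accuracy(perfect, truth, image_height=512) == 100.0
        none = [NavResult()] * 4
        assert line_accuracy(none, truth, image_height=512) == 0.0
        mixed = [self._nav(0.0), self._nav(8.0), self._nav(6.9), NavResult()]
        assert line_accuracy(mixed, truth, image_height=512) == 50.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            line_accuracy([NavResult()], [], image_height=512)


class TestRotationConsistency:
    def test_quarter_turn_preserves_fitted_angles(self, clean_params, rng):
        """Rotating the mask 90 deg (and scanning accordingly) rotates the lines."""
        params = clean_params.with_(row_angle=4.0)
        sample = synthetic.generate_scene(params, seed=1)
        lines = fit_all_rows(
            extract_feature_points(sample.mask, ScanConfig(h=8)),
            RansacConfig(),
            rng,
            image_shape=sample.mask.shape,
        )
        rotated_mask = np.ascontiguousarray(np.rot90(sample.mask))
        rotated_lines = fit_all_rows(
            extract_feature_points(rotated_mask, ScanConfig(h=8, orientation="vertical")),
            RansacConfig(separation_axis="x"),
            rng,
            image_shape=rotated_mask.shape,
        )
        assert len(rotated_lines) == len(lines) == 3
        for ln in lines:
            # counter-clockwise quarter turn of (dx, dy) is (-dy, dx)
            target = np.array([-ln.direction[1], ln.direction[0]])
            best = min(
                np.degrees(
                    np.arccos(np.clip(abs(target @ rl.direction), 0, 1))
                )
                for rl in rotated_lines
            )
            assert best < 0.5
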