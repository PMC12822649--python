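"""Baseline pit detector and detection-metric evaluation."""

import dataclasses

import numpy as np
import pytest

from foveloc.detector import (Detection, baseline_detect, evaluate_detections,
                              fovea_x_from_detection, iou, read_annotation,
                              write_annotation)
from foveloc.errors import ParameterError
from foveloc.scene import SceneParams, generate_scene

from oracles import brute_force_precision_recall


def _layered_image(surface_rows: np.ndarray, height: int = 120) -> np.ndarray:
    """Tissue below a given per-column surface row, background above."""
    rows = np.arange(height)[:, None]
    return np.where(rows >= surface_rows[None, :], 0.9, 0.05).astype(np.float32)


class TestBaselineDetect:
    def test_flat_retina_yields_none(self):
        assert baseline_detect(_layered_image(np.full(200, 40))) is None

    def test_blank_image_yields_none(self):
        assert baseline_detect(np.zeros((64, 64))) is None

    def test_noiseless_fovea_bscan_centre_is_exact(self, default_scene):
        truth = default_scene.truth
        det = baseline_detect(default_scene.volume.bscans[truth.fovea_bscan_index])
        assert det is not None
        assert fovea_x_from_detection(det) == truth.fovea_col_px
        assert det.confidence > 0
        r0, c0, r1, c1 = det.box
        assert 0 <= r0 < r1 and 0 <= c0 < c1

    def test_two_equal_pits_resolve_to_earliest_column(self):
        surface = np.full(240, 40.0)
        cols = np.arange(240)
        for centre in (60, 180):  # identical depth and width
            surface += 14 * np.exp(-0.5 * ((cols - centre) / 8.0) ** 2)
        det = baseline_detect(_layered_image(np.rint(surface).astype(int)))
        assert det is not None
        assert abs(fovea_x_from_detection(det) - 60) <= 1

    @pytest.mark.parametrize("shift", [1, 5, 20])
    def test_translation_equivariance(self, shift):
        base = SceneParams()
        centre = []
        for k in (0, shift):
            params = dataclasses.replace(
                base, fovea_center=(base.fovea_center[0]
                                    - k * base.mm_per_px_bscan_x,
                                    base.fovea_center[1]))
            scene = generate_scene(params)
            det = baseline_detect(
                scene.volume.bscans[scene.truth.fovea_bscan_index])
            centre.append(fovea_x_from_detection(det))
        assert centre[0] - centre[1] == shift

    def test_min_depth_threshold_suppresses_shallow_pits(self, default_scene):
        img = default_scene.volume.bscans[default_scene.truth.fovea_bscan_index]
        assert baseline_detect(img, min_pit_depth_px=1000.0) is None


@pytest.mark.parametrize("cols, expected", [
    ((100, 120), 110),
    ((0, 1), 0),
    ((10, 15), 12),  # centre pixel 12.5 -> lower middle
])
def test_fovea_x_centre_convention(cols, expected):
    det = Detection(box=(0, cols[0], 10, cols[1]), confidence=0.5)
    assert fovea_x_from_detection(det) == expected


class TestEvaluateDetections:
    def test_perfect_predictions(self):
        boxes = [[(0, 0, 10, 10)], [(5, 5, 9, 9), (20, 20, 30, 30)]]
        preds = [[Detection(box=b, confidence=0.9) for b in img]
                 for img in boxes]
        assert evaluate_detections(preds, boxes) == (1.0, 1.0)

    def test_counts_follow_the_formula(self):
        # 9 matching predictions plus one spurious box, nothing missed
        truths = [[(0, 0, 10, 10)] for _ in range(9)] + [[]]
        preds = [[Detection(box=(0, 0, 10, 10), confidence=0.8)]
                 for _ in range(9)]
        preds.append([Detection(box=(50, 50, 60, 60), confidence=0.9)])
        precision, recall = evaluate_detections(preds, truths)
        assert precision == pytest.approx(0.9)
        assert recall == pytest.approx(1.0)

    @pytest.mark.parametrize("bad", [0.0, -0.2, 1.5])
    def test_invalid_iou_threshold(self, bad):
        with pytest.raises(ParameterError):
            evaluate_detections([], [], iou_threshold=bad)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            preds, truths, raw = _random_instance(rng)
            got = evaluate_detections(preds, truths, 0.5)
            want = brute_force_precision_recall(raw, truths, 0.5)
            assert got == pytest.approx(want)

    def test_permutation_invariance_over_images(self):
        rng = np.random.default_rng(3)
        preds, truths, _ = _random_instance(rng, n_images=6)
        base = evaluate_detections(preds, truths, 0.5)
        order = rng.permutation(len(preds))
        shuffled = evaluate_detections([preds[i] for i in order],
                                       [truths[i] for i in order], 0.5)
        assert shuffled == pytest.approx(base)


def _random_instance(rng, n_images=4, max_boxes=5):
    preds, truths, raw = [], [], []
    for _ in range(n_images):
        gts = [_random_box(rng) for _ in range(rng.integers(0, max_boxes + 1))]
        ps = []
        for _ in range(rng.integers(0, max_boxes + 1)):
            if gts and rng.random() < 0.6:  # jittered copy of a truth box
                r0, c0, r1, c1 = gts[rng.integers(len(gts))]
                j = rng.integers(-2, 3, size=4)
                box = (r0 + j[0], c0 + j[1],
                       max(r0 + j[0] + 1, r1 + j[2]),
                       max(c0 + j[1] + 1, c1 + j[3]))
            else:
                box = _random_box(rng)
            ps.append((box, float(rng.random())))
        preds.append([Detection(box=b, confidence=c) for b, c in ps])
        raw.append(ps)
        truths.append(gts)
    return preds, truths, raw


def _random_box(rng):
    r0 = int(rng.integers(0, 40))
    c0 = int(rng.integers(0, 40))
    return (r0, c0, r0 + int(rng.integers(4, 15)), c0 + int(rng.integers(4, 15)))


def test_noiseless_scene_set_scores_perfectly():
    """Baseline detections on fovea B-scans of several noiseless scenes
    reach precision = recall = 1.0 at IoU 0.5 against the truth boxes."""
    preds, truths = [], []
    for seed in range(5):
        params = dataclasses.replace(
            SceneParams(), seed=seed,
            fovea_center=(0.3 * seed - 0.6, 1.2 - 0.2 * seed))
        scene = generate_scene(params)
        det = baseline_detect(scene.volume.bscans[scene.truth.fovea_bscan_index])
        preds.append([det] if det else [])
        truths.append([scene.truth.fovea_box])
    assert evaluate_detections(preds, truths, 0.5) == (1.0, 1.0)


def test_annotation_roundtrip(tmp_path):
    boxes = [(10, 20, 30, 60), (0, 0, 5, 5)]
    path = tmp_path / "img.txt"
    write_annotation(path, boxes, image_shape=(100, 200))
    assert read_annotation(path, image_shape=(100, 200)) == boxes


def test_iou_basic_values():
    assert iou((0, 0, 10, 10), (0, 0, 10, 10)) == 1.0
    assert iou((0, 0, 10, 10), (20, 20, 30, 30)) == 0.0
    assert iou((0, 0, 10, 10), (0, 5, 10, 15)) == pytest.approx(1 / 3)
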