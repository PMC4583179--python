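"""The 3x3 delta mask, per-pixel scoring, and whole-image edge maps."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage

from fuzzedge.detector import (
    DEFAULT_NEIGHBOR_ORDER,
    DetectorConfig,
    detect_edges,
    edge_score,
    extract_deltas,
    score_map,
)


def label_count(edges):
    _, n = ndimage.label(edges, structure=np.ones((3, 3)))
    return n


class TestExtractDeltas:
    def test_uniform_patch_gives_zero_deltas(self):
        img = np.full((5, 5), 100)
        assert np.array_equal(extract_deltas(img, 2, 2), np.zeros(8))

    def test_maximal_contrast(self):
        img = np.full((3, 3), 255)
        img[1, 1] = 0
        assert np.array_equal(extract_deltas(img, 1, 1), np.full(8, 255.0))

    def test_single_neighbour_difference_under_convention(self):
        img = np.full((3, 3), 100)
        img[0, 0] = 30  # NW neighbour = P1 under row-major ordering
        deltas = extract_deltas(img, 1, 1)
        assert deltas[0] == 70.0
        assert np.array_equal(deltas[1:], np.zeros(7))

    def test_border_coordinates_rejected(self):
        img = np.zeros((5, 5))
        for row, col in [(0, 2), (4, 2), (2, 0), (2, 4)]:
            with pytest.raises(ValueError):
                extract_deltas(img, row, col)


class TestEdgeScore:
    def test_flat_neighbourhood_scores_nonedge(self, detector_config):
        # no rule can fire (each needs two Higher memberships), else -> 1
        c = edge_score(np.zeros(8), detector_config)
        assert abs(c - 10.0) < 1.0

    def test_rule_one_pattern_scores_edge(self, detector_config):
        deltas = np.zeros(8)
        deltas[0] = deltas[1] = 255.0  # dP1, dP2 Higher; dP8 Lower
        c = edge_score(deltas, detector_config)
        assert abs(c - 245.0) < 1.0

    def test_all_ways_contrast_scores_nonedge(self, detector_config):
        """An isolated impulse has every delta Higher, so every rule's Lower
        antecedent is dead — the mechanism of impulse-noise rejection."""
        c = edge_score(np.full(8, 255.0), detector_config)
        assert abs(c - 10.0) < 1.0


class TestDetectEdges:
    def test_uniform_image_has_no_edges(self):
        for level in (0, 100, 255):
            edges = detect_edges(np.full((32, 32), level))
            assert not edges.any()

    def test_vertical_step_yields_single_thin_line(self):
        img = np.zeros((32, 32), dtype=int)
        img[:, 16:] = 255
        edges = detect_edges(img)
        rows, cols = np.nonzero(edges)
        assert set(np.unique(cols)) <= {15, 16}   # width <= 2 at the step
        assert set(rows) == set(range(1, 31))     # spans all interior rows
        assert label_count(edges) == 1

    def test_isolated_impulse_not_flagged(self):
        img = np.zeros((15, 15), dtype=int)
        img[7, 7] = 255
        edges, scores = detect_edges(img, return_scores=True)
        assert not edges[7, 7]
        assert not edges.any()
        # every pixel in the impulse neighbourhood agrees with the per-pixel oracle
        cfg = DetectorConfig()
        for r in range(6, 9):
            for c in range(6, 9):
                assert scores[r, c] == edge_score(extract_deltas(img, r, c), cfg)

    def test_matches_naive_per_pixel_oracle_exactly(self, rng, detector_config):
        for _ in range(5):
            img = rng.integers(0, 256, size=(16, 16))
            edges, scores = detect_edges(img, detector_config, return_scores=True)
            naive = np.zeros((16, 16), dtype=bool)
            for r in range(1, 15):
                for c in range(1, 15):
                    s = edge_score(extract_deltas(img, r, c), detector_config)
                    assert s == scores[r, c]
                    naive[r, c] = s >= detector_config.threshold
            assert np.array_equal(edges, naive)

    def test_global_intensity_shift_invariance(self, rng):
        img = rng.integers(40, 160, size=(24, 24))
        base = detect_edges(img)
        for k in (-40, 25, 90):
            assert np.array_equal(detect_edges(img + k), base)

    def test_mirror_with_relabelled_convention(self, rng):
        """Mirroring the image and the neighbour convention mirrors the map."""
        img = rng.integers(0, 256, size=(20, 20))
        mirror_order = tuple(
            {"NW": "NE", "NE": "NW", "W": "E", "E": "W", "SW": "SE", "SE": "SW"}.get(n, n)
            for n in DEFAULT_NEIGHBOR_ORDER
        )
        cfg = DetectorConfig()
        mirrored_cfg = DetectorConfig(neighbor_order=mirror_order)
        lhs = detect_edges(img[:, ::-1], mirrored_cfg)
        rhs = detect_edges(img, cfg)[:, ::-1]
        assert np.array_equal(lhs, rhs)
        assert lhs.sum() == rhs.sum()

    def test_threshold_monotonicity(self, rng):
        img = rng.integers(0, 256, size=(24, 24))
        thresholds = [60.0, 110.0, 160.0, 220.0]
        maps = [
            detect_edges(img, DetectorConfig(threshold=t)) for t in thresholds
        ]
        for lower, higher in zip(maps, maps[1:]):
            assert np.all(higher <= lower)  # raising threshold never adds pixels

    def test_border_never_flagged(self, rng):
        img = rng.integers(0, 256, size=(12, 12))
        edges = detect_edges(img, DetectorConfig(threshold=10.5))  # permissive
        assert not edges[0, :].any() and not edges[-1, :].any()
        assert not edges[:, 0].any() and not edges[:, -1].any()

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError):
            detect_edges(np.zeros((2, 2)))
        with pytest.raises(ValueError):
            detect_edges(np.zeros((3,)))


class TestDetectorConfig:
    def test_threshold_must_sit_between_output_centres(self):
        with pytest.raises(ValueError):
            DetectorConfig(threshold=9.0)
        with pytest.raises(ValueError):
            DetectorConfig(threshold=250.0)

    def test_neighbor_order_must_be_permutation(self):
        with pytest.raises(ValueError):
            DetectorConfig(neighbor_order=("NW",) * 8)

    def test_replace_threshold(self, detector_config):
        cfg = dataclasses.replace(detector_config, threshold=200.0)
        assert cfg.threshold == 200.0

    def test_score_map_border_carries_no_evidence_score(self, rng):
        img = rng.integers(0, 256, size=(8, 8))
        scores = score_map(img)
        assert scores[0, 0] == edge_score(np.zeros(8))
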