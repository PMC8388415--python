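"""Landmark I/O, computational landmarks, and score measurements."""

import math

import numpy as np
import pandas as pd
import pytest

from toothmarks.landmarks import (
    GeometryError,
    LandmarkDataset,
    MorphologikaError,
    ScoreProfile2D,
    compute_wall_landmarks,
    metrics_table,
    read_morphologika,
    read_tps,
    score_metrics,
    write_morphologika,
)


def _random_profile(rng):
    """A random valid V-shaped profile with straight walls."""
    wis = rng.uniform(0.3, 2.0)
    depth = rng.uniform(0.05, 0.8)
    off = rng.uniform(-0.3, 0.3) * wis
    poly = np.array([[0.0, 0.0], [wis / 2 + off, -depth], [wis, 0.0]])
    return compute_wall_landmarks(poly, (0, 1, 2))


class TestMorphologika:
    def test_round_trip_identity(self, tmp_path, rng):
        coords = rng.normal(size=(2, 7, 2))
        coords[:, :, 1] = -np.abs(coords[:, :, 1])  # keep below-chord shape
        # build simple valid profiles instead: straight V pair
        coords = np.stack([_random_profile(rng).landmarks for _ in range(2)])
        meta = pd.DataFrame(
            {"park": ["Cabarceno", "Flechas"],
             "captivity": ["captive", "wild"],
             "prey_size": ["large", "mixed"]},
            index=pd.Index(["a", "b"], name="specimen_id"))
        ds = LandmarkDataset(coords, ["a", "b"], meta)
        path = tmp_path / "scores.txt"
        write_morphologika(ds, path, precision=17)
        back = read_morphologika(path)
        assert back.shape == (2, 7, 2)
        np.testing.assert_array_equal(back.coords, ds.coords)
        assert list(back.metadata["captivity"]) == ["captive", "wild"]
        assert back.specimen_ids == ["a", "b"]

    def test_counts_from_generated_fixture(self, tmp_path, rng):
        coords = rng.normal(size=(3, 30, 3))
        ds = LandmarkDataset(coords, ["p1", "p2", "p3"])
        path = tmp_path / "pits.txt"
        write_morphologika(ds, path)
        back = read_morphologika(path)
        assert back.shape == (3, 30, 3)

    def test_missing_landmark_row_is_parse_error(self, tmp_path):
        text = "\n".join([
            "[individuals]", "1", "[landmarks]", "7", "[dimensions]", "2",
            "[names]", "s1", "[rawpoints]", "' s1",
            *("%d 0.0" % i for i in range(6)),  # only 6 of 7 rows
        ])
        path = tmp_path / "bad.txt"
        path.write_text(text)
        with pytest.raises(MorphologikaError, match="s1"):
            read_morphologika(path)

    def test_wrong_coordinate_count_names_line(self, tmp_path):
        text = "\n".join([
            "[individuals]", "1", "[landmarks]", "2", "[dimensions]", "2",
            "[rawpoints]", "' s1", "0.0 1.0", "0.0 1.0 2.0",
        ])
        path = tmp_path / "bad.txt"
        path.write_text(text)
        with pytest.raises(MorphologikaError, match=":10"):
            read_morphologika(path)

    def test_unknown_block_is_skipped(self, tmp_path, rng, caplog):
        coords = np.stack([_random_profile(rng).landmarks])
        ds = LandmarkDataset(coords, ["x"])
        path = tmp_path / "f.txt"
        write_morphologika(ds, path)
        path.write_text(path.read_text() + "\n[wireframe]\n1 2\n")
        back = read_morphologika(path)
        assert back.shape == (1, 7, 2)

    def test_tps_read(self, tmp_path):
        path = tmp_path / "f.tps"
        path.write_text(
            "LM=3\n0 0\n1 0\n1 1\nID=tri1\nSCALE=2.0\n"
            "LM=3\n0 0\n2 0\n2 2\nID=tri2\n")
        ds = read_tps(path)
        assert ds.shape == (2, 3, 2)
        np.testing.assert_allclose(ds.coords[0], [[0, 0], [2, 0], [2, 2]])
        assert ds.specimen_ids == ["tri1", "tri2"]


class TestWallLandmarks:
    def test_straight_v_thirds(self, symmetric_v):
        expected = np.array([
            [0, 0], [1 / 6, -1 / 6], [1 / 3, -1 / 3], [0.5, -0.5],
            [2 / 3, -1 / 3], [5 / 6, -1 / 6], [1, 0]])
        np.testing.assert_allclose(symmetric_v.landmarks, expected, atol=1e-12)

    def test_kinked_wall_arc_length_oracle(self):
        poly = np.array([[0.0, 0.0], [0.1, -0.4], [0.5, -0.5], [1.0, 0.0]])
        prof = compute_wall_landmarks(poly, (0, 2, 3))
        # oracle: cumulative segment sums along the kinked left wall
        left = poly[:3]
        seg = np.linalg.norm(np.diff(left, axis=0), axis=1)
        total = seg.sum()
        for lm, frac in [(prof.landmarks[1], 1 / 3), (prof.landmarks[2], 2 / 3)]:
            target = frac * total
            if target <= seg[0]:
                expect = left[0] + (target / seg[0]) * (left[1] - left[0])
            else:
                t = (target - seg[0]) / seg[1]
                expect = left[1] + t * (left[2] - left[1])
            np.testing.assert_allclose(lm, expect, atol=1e-12)
        # right wall is a single straight segment: exact thirds from the base
        np.testing.assert_allclose(
            prof.landmarks[4], poly[2] + (poly[3] - poly[2]) / 3, atol=1e-12)

    def test_zero_length_wall_is_geometry_error(self):
        poly = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0]])
        with pytest.raises(GeometryError):
            compute_wall_landmarks(poly, (0, 1, 2))

    def test_base_outside_shoulders_is_geometry_error(self):
        poly = np.array([[0.0, 0.0], [0.5, -0.5], [1.0, 0.0]])
        with pytest.raises(GeometryError):
            compute_wall_landmarks(poly, (1, 0, 2))


class TestScoreMetrics:
    def test_symmetric_v(self, symmetric_v):
        m = score_metrics(symmetric_v)
        assert m.WIS == pytest.approx(1.0, abs=1e-12)
        assert m.WIM == pytest.approx(2 / 3, abs=1e-12)
        assert m.WIB == pytest.approx(1 / 3, abs=1e-12)
        assert m.D == pytest.approx(0.5, abs=1e-12)
        assert m.LDC == pytest.approx(math.sqrt(0.5), abs=1e-12)
        assert m.RDC == pytest.approx(math.sqrt(0.5), abs=1e-12)
        assert m.OA == pytest.approx(90.0, abs=1e-10)

    def test_flat_profile_limits(self):
        lm = np.column_stack([np.linspace(0, 1, 7), np.zeros(7)])
        m = score_metrics(ScoreProfile2D(lm, "flat"))
        assert m.D == pytest.approx(0.0, abs=1e-12)
        assert m.OA == pytest.approx(180.0, abs=1e-8)

    def test_asymmetric_against_vector_oracle(self):
        poly = np.array([[0.0, 0.0], [0.3, -0.4], [1.0, 0.0]])
        prof = compute_wall_landmarks(poly, (0, 1, 2))
        m = score_metrics(prof)
        lm = prof.landmarks
        # independent coordinate-geometry oracle
        assert m.WIS == pytest.approx(np.hypot(*(lm[0] - lm[6])), abs=1e-12)
        assert m.WIM == pytest.approx(np.hypot(*(lm[1] - lm[5])), abs=1e-12)
        assert m.WIB == pytest.approx(np.hypot(*(lm[2] - lm[4])), abs=1e-12)
        assert m.LDC == pytest.approx(math.hypot(0.3, 0.4), abs=1e-12)
        assert m.RDC == pytest.approx(math.hypot(0.7, 0.4), abs=1e-12)
        assert m.D == pytest.approx(0.4, abs=1e-12)
        v1, v2 = lm[0] - lm[3], lm[6] - lm[3]
        oracle_oa = math.degrees(math.acos(
            v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))))
        assert m.OA == pytest.approx(oracle_oa, abs=1e-12)

    def test_coincident_shoulders_error(self):
        lm = np.zeros((7, 2))
        lm[3] = [0, -1]
        with pytest.raises((GeometryError, ValueError)):
            score_metrics(ScoreProfile2D(lm, "bad"))

    @pytest.mark.parametrize("kind", ["translate", "rotate", "reflect"])
    def test_rigid_motion_invariance(self, rng, kind):
        for _ in range(20):
            prof = _random_profile(rng)
            m0 = score_metrics(prof)
            lm = prof.landmarks.copy()
            if kind == "translate":
                lm = lm + rng.normal(size=2)
            elif kind == "rotate":
                th = rng.uniform(0, 2 * np.pi)
                R = np.array([[np.cos(th), -np.sin(th)],
                              [np.sin(th), np.cos(th)]])
                lm = lm @ R.T
            else:
                lm = lm * np.array([-1.0, 1.0])  # mirror across y-axis
            m1 = score_metrics(ScoreProfile2D(lm, "t"))
            for k, v in m0.as_dict().items():
                assert getattr(m1, k) == pytest.approx(v, abs=1e-9), k

    def test_scaling_scales_lengths_not_angle(self, rng):
        prof = _random_profile(rng)
        m0 = score_metrics(prof)
        s = 3.7
        m1 = score_metrics(ScoreProfile2D(prof.landmarks * s, "s"))
        for k in ("WIS", "WIM", "WIB", "D", "LDC", "RDC"):
            assert getattr(m1, k) == pytest.approx(s * getattr(m0, k), rel=1e-12)
        assert m1.OA == pytest.approx(m0.OA, abs=1e-10)

    def test_straight_wall_width_ratios(self, rng):
        for _ in range(20):
            m = score_metrics(_random_profile(rng))
            assert m.WIM == pytest.approx(2 / 3 * m.WIS, rel=1e-9)
            assert m.WIB == pytest.approx(1 / 3 * m.WIS, rel=1e-9)
            assert m.WIS >= m.WIM >= m.WIB

    def test_metrics_table_joins_metadata(self, rng):
        coords = np.stack([_random_profile(rng).landmarks for _ in range(3)])
        meta = pd.DataFrame({"park": ["a", "b", "c"]},
                            index=pd.Index(["s1", "s2", "s3"],
                                           name="specimen_id"))
        table = metrics_table(LandmarkDataset(coords, ["s1", "s2", "s3"], meta))
        assert set(table.columns) == {"WIS", "WIM", "WIB", "D", "LDC", "RDC",
                                      "OA", "park"}
        assert len(table) == 3
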