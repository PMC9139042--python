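import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import gaitskew as gs
from gaitskew.djnp import POINT_COLUMNS, SourceMeta
from gaitskew.errors import InsufficientDataError
from gaitskew.posture_metrics import side_centroids

from conftest import random_djnp


def _djnp_from_points(rows, n_samples, frame_size=(1080, 1920)):
    pts = pd.DataFrame(rows, columns=POINT_COLUMNS)
    meta = SourceMeta(frame_width=frame_size[0], frame_height=frame_size[1])
    return gs.DJNP(pts, n_samples, gs.COCO18, meta)


class TestBuildIPI:
    def test_single_point_occupies_origin_block(self):
        d = _djnp_from_points([[0, 0, 0.0, 0.0, 0.0]], 1)
        g = gs.build_ipi(d, block_edge=40)
        assert g.occupancy[0, 0, 0] == 1
        assert g.occupancy.sum() == 1
        assert g.n_cols == 27  # 1080 / 40

    def test_empty_djnp_all_zero(self):
        d = _djnp_from_points([], 3)
        g = gs.build_ipi(d, 40)
        assert g.occupancy.sum() == 0
        assert g.occupancy.shape == (3, 48, 27)

    def test_matches_brute_force_point_in_block(self, rng):
        d = random_djnp(rng, n_samples=5)
        g = gs.build_ipi(d, 40)
        brute = np.zeros_like(g.occupancy)
        for _, p in d.points.iterrows():
            for r in range(g.n_rows):
                for c in range(g.n_cols):
                    if (c * 40 <= p["x"] < (c + 1) * 40) and (r * 40 <= p["y"] < (r + 1) * 40):
                        brute[int(p["sample_index"]), r, c] = 1
        np.testing.assert_array_equal(g.occupancy, brute)

    def test_oversized_block_degenerates_with_warning(self):
        d = _djnp_from_points([[0, 0, 0.0, 10.0, 10.0]], 1)
        with pytest.warns(UserWarning, match="single block"):
            g = gs.build_ipi(d, 5000)
        assert g.occupancy.shape == (1, 1, 1)

    def test_nonpositive_edge_rejected(self):
        with pytest.raises(ValueError):
            gs.build_ipi(_djnp_from_points([], 1), 0)


class TestFuseIPI:
    def test_dimension_mismatch_raises(self):
        d = _djnp_from_points([], 1, frame_size=(100, 100))
        g = gs.build_ipi(d, 10)
        with pytest.raises(ValueError):
            gs.fuse_ipi_djnp(g, np.zeros((50, 50), dtype=np.uint8))

    def test_empty_and_full_occupancy(self):
        d = _djnp_from_points([], 1, frame_size=(100, 100))
        g = gs.build_ipi(d, 10)
        img = np.zeros((100, 100), dtype=np.uint8)
        fused = gs.fuse_ipi_djnp(g, img)
        assert fused[0, :].min() > 0  # grid line
        assert fused[5, 5] == 0  # unoccupied interior stays background
        g.occupancy[:] = 1
        full = gs.fuse_ipi_djnp(g, img)
        assert (full[5, 5] > 0) and (full > 0).mean() == 1.0

    def test_deterministic(self, straight_walk):
        g = gs.build_ipi(straight_walk.djnp, 40)
        img = gs.render_djnp(straight_walk.djnp)
        np.testing.assert_array_equal(gs.fuse_ipi_djnp(g, img), gs.fuse_ipi_djnp(g, img))


class TestSideAngle:
    def _trace(self, xs, ys, joint=10):
        rows = [[joint, i, i * 0.3, x, y] for i, (x, y) in enumerate(zip(xs, ys))]
        return _djnp_from_points(rows, len(xs))

    def test_vertical_trace_zero_degrees(self):
        d = self._trace([500] * 5, [100, 200, 300, 400, 500])
        assert gs.side_angle(d, "right") == pytest.approx(0.0, abs=1e-9)

    def test_diagonal_trace_45_degrees(self):
        d = self._trace([100, 200, 300], [100, 200, 300])
        assert gs.side_angle(d, "right") == pytest.approx(45.0)

    def test_insufficient_samples_raise(self):
        d = self._trace([100], [100])
        with pytest.raises(InsufficientDataError):
            gs.side_angle(d, "right")
        with pytest.raises(InsufficientDataError):
            gs.side_angle(d, "left")  # no left-side joints at all

    def test_recovers_simulator_drift_within_one_degree(self, skewed_walk):
        est = gs.estimate_drift_angle(skewed_walk.djnp, direction="toward")
        assert est == pytest.approx(8.0, abs=1.0)

    def test_recovery_away_and_negative(self):
        walk = gs.simulate_walk(
            gs.WalkConfig(noise_sd=0.0, skew_angle=-6.0, direction="away"), seed=9
        )
        est = gs.estimate_drift_angle(walk.djnp, direction="away")
        assert est == pytest.approx(-6.0, abs=1.0)


class TestRatios:
    @pytest.mark.parametrize("tl,tr,expected", [(10, 10, 1.0), (10, 8, 1.25), (4, 8, 0.5)])
    def test_skew_ratio_values(self, tl, tr, expected):
        assert gs.skew_ratio(tl, tr) == pytest.approx(expected)

    def test_skew_ratio_sentinels(self):
        assert gs.skew_ratio(0, 0) == 1.0
        assert math.isinf(gs.skew_ratio(10, 0))

    @given(st.floats(1e-6, 90.0))
    def test_equal_angles_give_unit_ratio(self, a):
        assert gs.skew_ratio(a, a) == 1.0

    @pytest.mark.parametrize(
        "sr,expected", [(1.0, "straight"), (1.25, "right"), (0.5, "left"),
                        (1.04, "straight"), (math.inf, "right")]
    )
    def test_classify_skew(self, sr, expected):
        assert gs.classify_skew(sr, epsilon=0.05) == expected

    @pytest.mark.parametrize("dr,dl,md,label", [(5, 5, 1.0, "straight"),
                                                (6, 4, 1.5, "right"),
                                                (2, 8, 0.25, "left")])
    def test_dominance_ratio(self, dr, dl, md, label):
        ratio = gs.dominance_ratio(dr, dl)
        assert ratio == pytest.approx(md)
        assert gs.classify_skew(ratio) == label

    def test_dominance_sentinels(self):
        assert gs.dominance_ratio(0, 0) == 1.0
        assert math.isinf(gs.dominance_ratio(3, 0))

    @pytest.mark.parametrize("path,t,v", [(5, 10, 0.5), (5, 5, 1.0), (5, 7.4, 0.6757)])
    def test_walking_velocity(self, path, t, v):
        assert gs.walking_velocity(path, t) == pytest.approx(v, abs=1e-4)

    def test_walking_velocity_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            gs.walking_velocity(0, 5)


class TestSideDisplacement:
    def test_identical_consecutive_samples_zero(self):
        rows = [[10, 0, 0.0, 100.0, 100.0], [10, 1, 0.3, 100.0, 100.0]]
        d = _djnp_from_points(rows, 2)
        assert gs.side_displacement(d, "right", 1) == 0.0

    def test_three_four_five_triangle(self):
        rows = [[10, 0, 0.0, 100.0, 100.0], [10, 1, 0.3, 103.0, 104.0]]
        d = _djnp_from_points(rows, 2)
        assert gs.side_displacement(d, "right", 1) == pytest.approx(5.0)

    def test_missing_side_raises(self):
        rows = [[10, 0, 0.0, 100.0, 100.0], [0, 1, 0.3, 100.0, 100.0]]  # nose only at s1
        d = _djnp_from_points(rows, 2)
        with pytest.raises(InsufficientDataError):
            gs.side_displacement(d, "right", 1)

    def test_matches_simulator_centroid_distances(self, straight_walk):
        d = straight_walk.djnp
        cen = side_centroids(d, "left").set_index("sample_index")
        for i in [1, 5, 10]:
            oracle = float(
                np.hypot(*(cen.loc[i, ["x", "y"]] - cen.loc[i - 1, ["x", "y"]]))
            )
            assert gs.side_displacement(d, "left", i) == pytest.approx(oracle, abs=1e-6)


class TestSkewInvariants:
    def test_mirror_antisymmetry_on_random_djnps(self, rng):
        """Horizontal mirroring maps SR -> 1/SR, MD -> 1/MD and swaps labels."""
        swap = {"left": "right", "right": "left", "straight": "straight"}
        for _ in range(5):
            d = random_djnp(rng, n_samples=5)
            m = gs.compute_skew_metrics(d)
            mm = gs.compute_skew_metrics(gs.mirror_djnp(d))
            assert mm.sr == pytest.approx(1.0 / m.sr, rel=1e-9)
            assert mm.skew_label == swap[m.skew_label]
            for a, b in zip(m.md, mm.md):
                if a is not None:
                    assert b == pytest.approx(1.0 / a, rel=1e-9)

    def test_straight_walker_sr_and_md_unity(self, straight_walk):
        m = gs.compute_skew_metrics(straight_walk.djnp)
        assert m.sr == pytest.approx(1.0, abs=0.02)
        assert m.skew_label == "straight"
        assert all(x == pytest.approx(1.0, abs=0.02) for x in m.md)

    def test_skewed_walker_angle_and_dominance_asymmetry(self, skewed_walk):
        """Drift toward image right tilts the left-side trace further from
        vertical (SR > 1) and makes the left side sweep the longer path per
        interval (MD < 1): the dominant displacement side is contralateral
        to the skew direction."""
        m = gs.compute_skew_metrics(skewed_walk.djnp)
        assert m.theta_l > m.theta_r
        assert m.sr > 1.0
        mds = [x for x in m.md if x is not None]
        assert np.mean(mds) < 1.0

    def test_metrics_frame_schema(self, straight_walk):
        df = gs.compute_skew_metrics(straight_walk.djnp).to_frame()
        assert list(df.columns) == [
            "sample_index", "theta_l", "theta_r", "sr", "d_r", "d_l", "md", "label"
        ]
        assert len(df) == straight_walk.djnp.n_samples - 1
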