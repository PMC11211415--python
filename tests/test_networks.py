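"""Sphere-sampling probe geometry and nearest-node network scoring."""

import numpy as np
import pandas as pd
import pytest

from tmstraj.networks import (
    DEFAULT_NETWORK_GROUPS,
    class_network_summary,
    count_networks,
    nearest_labels,
    probe_points,
    rotation_sensitivity,
    score_cohort,
)
from tmstraj.simulate import POWER_NETWORK_LABELS, generate_atlas


def atlas_from(coords, labels, node_ids=None):
    coords = np.asarray(coords, dtype=float)
    return pd.DataFrame(
        {
            "node_id": node_ids if node_ids is not None else np.arange(len(coords)),
            "x_mni_mm": coords[:, 0],
            "y_mni_mm": coords[:, 1],
            "z_mni_mm": coords[:, 2],
            "network_label": labels,
        }
    )


class TestProbePoints:
    def test_exact_count_and_target_first(self):
        pts = probe_points((1.0, 2.0, 3.0), s=2.5, seed=0)
        assert pts.shape == (401, 3)
        assert np.allclose(pts[0], (1.0, 2.0, 3.0))

    def test_twenty_spheres_with_prescribed_radii(self):
        s = 3.7
        pts = probe_points((0, 0, 0), s=s, seed=1)
        r = np.linalg.norm(pts[1:], axis=1)
        expected = np.repeat((np.arange(1, 21) / 10.0) * s, 20)
        assert np.allclose(np.sort(r), np.sort(expected), atol=1e-9)
        assert r.max() == pytest.approx(2.0 * s, abs=1e-9)
        assert r.min() == pytest.approx(0.1 * s, abs=1e-9)

    def test_zero_dispersion_collapses_to_target(self):
        pts = probe_points((5.0, -1.0, 0.0), s=0.0, seed=3)
        assert np.allclose(pts, (5.0, -1.0, 0.0))

    def test_deterministic_per_seed(self):
        a = probe_points((0, 0, 0), 1.0, seed=9)
        b = probe_points((0, 0, 0), 1.0, seed=9)
        c = probe_points((0, 0, 0), 1.0, seed=10)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)


class TestNearestLabels:
    def test_probe_on_node(self):
        atlas = atlas_from([(0, 0, 0), (6, 0, 0)], ["x", "y"])
        assert nearest_labels([(6, 0, 0)], atlas) == ["y"]

    def test_two_node_split(self):
        atlas = atlas_from([(0, 0, 0), (6, 0, 0)], ["x", "y"])
        assert nearest_labels([(2, 0, 0), (4, 0, 0)], atlas) == ["x", "y"]

    def test_tie_breaks_to_lowest_node_id(self):
        atlas = atlas_from([(0, 0, 0), (6, 0, 0)], ["x", "y"], node_ids=[5, 2])
        # (3,0,0) equidistant; node_id 2 is label "y"
        assert nearest_labels([(3, 0, 0)], atlas) == ["y"]

    def test_empty_atlas_rejected(self):
        with pytest.raises(ValueError):
            nearest_labels([(0, 0, 0)], atlas_from(np.empty((0, 3)), []))

    def test_matches_bruteforce_on_random_atlases(self):
        rng = np.random.default_rng(8)
        for _ in range(3):
            n = rng.integers(10, 300)
            coords = rng.uniform(-80, 80, size=(n, 3))
            labels = rng.choice(list("abcdefgh"), size=n)
            atlas = atlas_from(coords, labels)
            pts = rng.uniform(-80, 80, size=(50, 3))
            got = nearest_labels(pts, atlas)
            d = np.linalg.norm(pts[:, None, :] - coords[None, :, :], axis=2)
            expected = [labels[j] for j in d.argmin(axis=1)]
            assert got == expected


class TestCountNetworks:
    def test_single_label_atlas(self):
        atlas = atlas_from([(0, 0, 0), (50, 0, 0)], ["only", "only"])
        assert count_networks((10, 10, 10), 5.0, atlas, seed=0).n_networks == 1

    def test_two_node_atlas_radius_controls_reach(self):
        atlas = atlas_from([(0, 0, 0), (6, 0, 0)], ["x", "y"])
        # s=1: max radius 2 < 3 -> only "x"; s=4: max radius 8 crosses 3
        assert count_networks((0, 0, 0), 1.0, atlas, seed=0).n_networks == 1
        assert count_networks((0, 0, 0), 4.0, atlas, seed=0).n_networks == 2

    def test_agrees_with_bruteforce(self):
        rng = np.random.default_rng(12)
        coords = rng.uniform(-40, 40, size=(120, 3))
        labels = rng.choice(list("pqrstu"), size=120)
        atlas = atlas_from(coords, labels)
        target, s, seed = (5.0, -3.0, 12.0), 6.0, 77
        got = count_networks(target, s, atlas, seed=seed)
        pts = probe_points(target, s, seed=seed)
        d = np.linalg.norm(pts[:, None, :] - coords[None, :, :], axis=2)
        expected = {labels[j] for j in d.argmin(axis=1)}
        assert got.labels_hit == expected
        assert got.n_networks == len(expected)

    def test_monotone_in_dispersion(self):
        rng = np.random.default_rng(5)
        for atlas_seed in (0, 1):
            atlas = generate_atlas(150, POWER_NETWORK_LABELS, seed=atlas_seed)
            target = atlas[["x_mni_mm", "y_mni_mm", "z_mni_mm"]].iloc[3].to_numpy()
            counts = [
                count_networks(target, s, atlas, seed=4).n_networks
                for s in (0.5, 1, 2, 4, 8, 16)
            ]
            assert counts == sorted(counts)

    def test_group_flags_from_grouping_table(self):
        atlas = atlas_from(
            [(0, 0, 0), (100, 100, 100)], ["default mode", "salience"]
        )
        score = count_networks((0, 0, 0), 1.0, atlas, seed=0)
        assert score.group_flags == {"ecn": False, "dmn": True, "van": False}
        both = count_networks((50, 50, 50), 60.0, atlas, seed=0)
        assert both.group_flags["dmn"] and both.group_flags["van"]
        assert both.n_networks == 2

    def test_labels_compared_case_insensitively(self):
        atlas = atlas_from([(0, 0, 0)], ["Default Mode"])
        score = count_networks((0, 0, 0), 1.0, atlas, seed=0)
        assert score.group_flags["dmn"]

    def test_bounds(self):
        atlas = generate_atlas(40, ("a", "b", "c"), seed=2)
        score = count_networks((0, 0, 60), 10.0, atlas, seed=1)
        assert 1 <= score.n_networks <= 3


def test_rotation_sensitivity_brackets_the_count():
    atlas = generate_atlas(120, ("a", "b", "c", "d"), seed=6)
    target = atlas[["x_mni_mm", "y_mni_mm", "z_mni_mm"]].iloc[0].to_numpy()
    out = rotation_sensitivity(target, 6.0, atlas, n_rotations=20, seed=3)
    assert out["min"] <= out["mean"] <= out["max"]
    assert out["sd"] >= 0
    # the count cannot vary by rotation when every node shares one label
    one = atlas.assign(network_label="only")
    flat = rotation_sensitivity(target, 6.0, one, n_rotations=10, seed=3)
    assert flat["sd"] == 0 and flat["min"] == flat["max"] == 1


class TestClassSummary:
    def _scores(self, counts, classes):
        return (
            pd.DataFrame(
                {
                    "subject_id": np.arange(len(counts)),
                    "n_networks": counts,
                    "ecn": True,
                    "dmn": False,
                    "van": False,
                }
            ),
            pd.Series(classes, index=pd.Index(np.arange(len(counts)), name="subject_id")),
        )

    def test_all_single_network(self):
        scores, cls = self._scores([1, 1, 1, 1], [0, 0, 1, 1])
        out = class_network_summary(scores, cls)
        assert (out["pct_multi_network"] == 0).all()

    def test_two_subject_class_aggregation(self):
        scores, cls = self._scores([1, 3], [0, 0])
        out = class_network_summary(scores, cls)
        assert out.loc[0, "mean_n_networks"] == pytest.approx(2.0)
        assert out.loc[0, "pct_multi_network"] == pytest.approx(50.0)
        assert out.loc[0, "pct_ecn"] == pytest.approx(100.0)

    def test_order_invariance(self):
        scores, cls = self._scores([1, 2, 3, 4], [0, 1, 0, 1])
        out1 = class_network_summary(scores, cls)
        perm = scores.iloc[[3, 1, 0, 2]].reset_index(drop=True)
        out2 = class_network_summary(perm, cls)
        pd.testing.assert_frame_equal(out1, out2)

    def test_empty_class_flagged(self):
        scores, cls = self._scores([1, 2], [0, 0])
        cls = pd.concat([cls, pd.Series([2], index=pd.Index([99], name="subject_id"))])
        out = class_network_summary(scores, cls)
        assert out.loc[out["class"] == 1, "empty"].item()


class TestScoreCohort:
    def test_deterministic_and_skips_missing_dispersion(self):
        atlas = generate_atlas(80, ("a", "b", "c", "d"), seed=0)
        targets = pd.DataFrame(
            {"subject_id": [0, 1, 2], "x": [0, 5, -5], "y": [60, 60, 60], "z": [10, 0, 5]}
        )
        disp = pd.DataFrame(
            {"subject_id": [0, 1, 2], "sd_dist_session1_mm": [4.0, np.nan, 2.0]}
        )
        a = score_cohort(targets, disp, atlas, seed=3)
        b = score_cohort(targets, disp, atlas, seed=3)
        pd.testing.assert_frame_equal(a, b)
        assert set(a["subject_id"]) == {0, 2}
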