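"""Cluster packing, labeling, concentration and shell detector."""

import numpy as np
import pytest
from scipy.spatial import cKDTree
from scipy.stats import kstest

from nanodose.geometry import (
    NPCluster,
    PackingInfeasibleError,
    build_shell_detector,
    check_overlaps,
    fe_concentration,
    generate_cluster,
    label_random,
    sample_decay_origin,
)
from nanodose.io import read_cluster_csv, write_cluster_csv


class TestGenerateCluster:
    def test_singleton_at_center(self):
        cl = generate_cluster(n=1, box_nm=1000.0, seed=0)
        np.testing.assert_array_equal(cl.centers_nm, [[0.0, 0.0, 0.0]])
        assert not check_overlaps(cl)

    def test_pair_gap_bounded_by_sd_max(self):
        cl = generate_cluster(n=2, box_nm=1000.0, sd_max_nm=1.0, seed=1)
        gap = np.linalg.norm(cl.centers_nm[1] - cl.centers_nm[0]) - 17.0
        assert 0.0 < gap <= 1.0

    @pytest.mark.parametrize("seed", range(3))
    @pytest.mark.parametrize("sd", [0.0, 1.0, 50.0])
    def test_default_cluster_invariants(self, seed, sd):
        cl = generate_cluster(n=500, box_nm=3500.0, sd_max_nm=sd, seed=seed)
        assert not check_overlaps(cl)          # brute-force all-pairs
        half = 3500.0 / 2 - 8.5
        assert np.all(np.abs(cl.centers_nm) <= half)
        gaps = cl.nearest_neighbor_gaps()
        assert np.all(gaps <= sd + 1e-6)
        assert np.all(gaps > 0)

    def test_bitwise_seed_reproducibility(self):
        a = generate_cluster(n=100, sd_max_nm=10.0, seed=42)
        b = generate_cluster(n=100, sd_max_nm=10.0, seed=42)
        np.testing.assert_array_equal(a.centers_nm, b.centers_nm)

    def test_packing_failure_reports_achieved_count(self):
        with pytest.raises((PackingInfeasibleError, ValueError)):
            generate_cluster(n=200, box_nm=80.0, sd_max_nm=0.0, seed=0)


class TestCheckOverlaps:
    def test_touching_pair_is_clear(self):
        cl = NPCluster(np.array([[0, 0, 0], [17.1, 0, 0]], dtype=float),
                       np.zeros(2, bool), 1000.0, 1.0, 0)
        assert check_overlaps(cl) == []

    def test_overlapping_pair_is_flagged(self):
        cl = NPCluster(np.array([[0, 0, 0], [16.9, 0, 0]], dtype=float),
                       np.zeros(2, bool), 1000.0, 1.0, 0)
        assert len(check_overlaps(cl)) == 1

    def test_agrees_with_independent_tree_implementation(self):
        cl = generate_cluster(n=100, box_nm=2000.0, sd_max_nm=5.0, seed=5)
        tree = cKDTree(cl.centers_nm)
        pairs = tree.query_pairs(2 * cl.outer_radius_nm)
        assert len(check_overlaps(cl)) == len(pairs) == 0


class TestLabelRandom:
    def test_all_and_none(self):
        cl = generate_cluster(n=20, box_nm=1000.0, sd_max_nm=5.0, seed=2)
        assert label_random(cl, 20).labeled.all()
        assert not label_random(cl, 0).labeled.any()

    def test_too_many_raises(self):
        cl = generate_cluster(n=5, box_nm=1000.0, sd_max_nm=5.0, seed=2)
        with pytest.raises(ValueError):
            label_random(cl, 6)

    def test_uniform_selection_frequency(self):
        cl = generate_cluster(n=100, box_nm=2500.0, sd_max_nm=10.0, seed=3)
        counts = np.zeros(100)
        n_trials = 2000
        for s in range(n_trials):
            counts += label_random(cl, 10, seed=s).labeled
        p = 0.1
        sigma = np.sqrt(n_trials * p * (1 - p))
        assert np.all(np.abs(counts - n_trials * p) < 4.5 * sigma)


class TestFeConcentration:
    def test_empty_cluster_zero(self):
        cl = NPCluster(np.empty((0, 3)), np.empty(0, bool), 3500.0, 0.0, 0)
        assert fe_concentration(cl) == 0.0

    def test_default_conditions_near_0p1_mM(self):
        cl = generate_cluster(n=500, box_nm=3500.0, sd_max_nm=10.0, seed=0)
        assert fe_concentration(cl) == pytest.approx(0.1, abs=0.02)

    def test_closed_form_value(self):
        cl = generate_cluster(n=500, box_nm=3500.0, sd_max_nm=10.0, seed=0)
        expected = 500 * 5874 / (6.02214076e23 * 4.2875e-14) * 1e3
        assert fe_concentration(cl) == pytest.approx(expected, rel=1e-6)

    def test_translation_invariance_and_volume_scaling(self):
        cl = generate_cluster(n=50, box_nm=2000.0, sd_max_nm=10.0, seed=1)
        shifted = NPCluster(cl.centers_nm + 100.0, cl.labeled, cl.box_nm,
                            cl.sd_max_nm, cl.seed)
        assert fe_concentration(shifted) == fe_concentration(cl)
        bigger = NPCluster(cl.centers_nm, cl.labeled, cl.box_nm * 2,
                           cl.sd_max_nm, cl.seed)
        assert fe_concentration(bigger) == pytest.approx(
            fe_concentration(cl) / 8.0)


class TestDecayOrigin:
    def test_support_and_radial_density(self, rng, small_cluster):
        idx = small_cluster.labeled_indices[0]
        pts = sample_decay_origin(small_cluster, idx, rng, 20_000)
        r = np.linalg.norm(pts - small_cluster.centers_nm[idx], axis=1)
        assert np.all((r >= 3.0) & (r <= 4.0))
        # r^2 density <=> r^3 uniform on [27, 64]
        u = (r**3 - 27.0) / (64.0 - 27.0)
        assert kstest(u, "uniform").pvalue > 0.01

    def test_unlabeled_index_raises(self, rng, small_cluster):
        unlabeled = int(np.flatnonzero(~small_cluster.labeled)[0])
        with pytest.raises(ValueError):
            sample_decay_origin(small_cluster, unlabeled, rng)

    def test_degenerate_annulus(self, rng):
        from nanodose.geometry import sample_annulus
        pts = sample_annulus(np.zeros(3), 3.5, 3.5, rng, 100)
        r = np.linalg.norm(pts, axis=1)
        np.testing.assert_allclose(r, 3.5, atol=1e-9)


class TestShellDetector:
    def test_default_has_92_shells(self):
        det = build_shell_detector()
        assert det.n_shells == 92
        assert det.inner_nm == 8.5 and det.outer_nm == 100.0

    def test_volumes_telescope(self):
        det = build_shell_detector()
        total = 4 / 3 * np.pi * (100.0**3 - 8.5**3)
        assert det.shell_volumes_nm3().sum() == pytest.approx(total, rel=1e-12)

    def test_single_shell(self):
        det = build_shell_detector(inner_nm=10.0, width_nm=40.0, outer_nm=50.0)
        assert det.n_shells == 1

    def test_shell_index_classification(self):
        det = build_shell_detector()
        pts = np.array([[0, 0, 5.0], [0, 0, 8.6], [0, 0, 99.9], [0, 0, 150.0]])
        idx = det.shell_index(pts)
        np.testing.assert_array_equal(idx, [-1, 0, 91, 92])

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            build_shell_detector(inner_nm=50.0, outer_nm=10.0)


def test_cluster_csv_round_trip(tmp_path, small_cluster):
    path = tmp_path / "cluster.csv"
    write_cluster_csv(small_cluster, path)
    back = read_cluster_csv(path)
    np.testing.assert_allclose(back.centers_nm, small_cluster.centers_nm,
                               rtol=1e-9)
    np.testing.assert_array_equal(back.labeled, small_cluster.labeled)
    assert back.box_nm == small_cluster.box_nm
    assert back.sd_max_nm == small_cluster.sd_max_nm
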