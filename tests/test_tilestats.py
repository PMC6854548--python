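"""Dual-criteria tile statistics, cluster-extent null, behavioural tests."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from oscbeam import (apply_cluster_threshold, behavioural_tests, cluster_null,
                     dual_criteria_mask, label_clusters, min_cluster_size,
                     simulate_behaviour, tile_condition_test)
from oscbeam.tilestats import TileTestResult


def flood_fill_components(mask, connectivity):
    """Brute-force BFS connected components oracle."""
    mask = np.asarray(mask, bool)
    if connectivity == 4:
        steps = [(1, 0), (-1, 0), (0, 1), (0, -1)]
    else:
        steps = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)
                 if (di, dj) != (0, 0)]
    seen = np.zeros_like(mask)
    comps = []
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        queue, comp = [start], set()
        seen[start] = True
        while queue:
            i, j = queue.pop()
            comp.add((i, j))
            for di, dj in steps:
                ni, nj = i + di, j + dj
                if (0 <= ni < mask.shape[0] and 0 <= nj < mask.shape[1]
                        and mask[ni, nj] and not seen[ni, nj]):
                    seen[ni, nj] = True
                    queue.append((ni, nj))
        comps.append(comp)
    return comps


def exact_max_cluster_distribution(shape, n_fill, connectivity):
    """Enumerate every placement of n_fill tiles; exact P(max size = k)."""
    n_tiles = int(np.prod(shape))
    counts = np.zeros(n_tiles + 1)
    for combo in itertools.combinations(range(n_tiles), n_fill):
        mask = np.zeros(n_tiles, bool)
        mask[list(combo)] = True
        comps = flood_fill_components(mask.reshape(shape), connectivity)
        counts[max((len(c) for c in comps), default=0)] += 1
    return counts / comb(n_tiles, n_fill)


class TestTileTests:
    def test_identical_conditions_give_null_stats(self, rng):
        grids = rng.normal(size=(5, 6, 4))
        res = tile_condition_test(grids, grids.copy())
        np.testing.assert_array_equal(res.t_diff, 0.0)
        np.testing.assert_array_equal(res.p_diff, 1.0)
        assert res.df == 4

    def test_hand_computed_paired_t(self):
        a = np.zeros((3, 1, 1))
        b = np.zeros((3, 1, 1))
        a[:, 0, 0] = [2.0, 3.0, 4.0]
        b[:, 0, 0] = [1.0, 1.0, 1.0]
        res = tile_condition_test(a, b)
        assert res.t_diff[0, 0] == pytest.approx(2.0 * np.sqrt(3.0), abs=1e-9)
        assert res.mean_diff[0, 0] == pytest.approx(2.0)

    def test_participant_order_invariance(self, rng):
        a = rng.normal(size=(7, 5, 3))
        b = rng.normal(size=(7, 5, 3))
        perm = np.random.default_rng(1).permutation(7)
        r1 = tile_condition_test(a, b)
        r2 = tile_condition_test(a[perm], b[perm])
        np.testing.assert_allclose(r1.t_diff, r2.t_diff, rtol=1e-10)
        np.testing.assert_allclose(r1.p_base_a, r2.p_base_a, rtol=1e-10)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="shape"):
            tile_condition_test(rng.normal(size=(4, 3, 3)),
                                rng.normal(size=(4, 3, 2)))


class TestDualCriteria:
    def _result(self, p_diff, p_a, p_b):
        shape = np.shape(p_diff)
        z = np.zeros(shape)
        return TileTestResult(mean_diff=z, t_diff=z,
                              p_diff=np.asarray(p_diff),
                              p_base_a=np.asarray(p_a),
                              p_base_b=np.asarray(p_b), n_participants=19)

    def test_difference_alone_insufficient(self):
        res = self._result([[0.04]], [[0.5]], [[0.5]])
        assert not dual_criteria_mask(res)[0, 0]

    def test_difference_plus_one_baseline_sufficient(self):
        res = self._result([[0.04]], [[0.005]], [[0.5]])
        assert dual_criteria_mask(res)[0, 0]
        res = self._result([[0.04]], [[0.5]], [[0.005]])
        assert dual_criteria_mask(res)[0, 0]

    def test_thresholds_are_strict(self):
        res = self._result([[0.05]], [[0.005]], [[0.005]])
        assert not dual_criteria_mask(res)[0, 0]
        res = self._result([[0.04]], [[0.01]], [[0.01]])
        assert not dual_criteria_mask(res)[0, 0]


class TestClusters:
    def test_run_of_six_is_one_cluster(self):
        mask = np.zeros((1, 8), bool)
        mask[0, 1:7] = True
        labels, sizes = label_clusters(mask, 4)
        assert sizes == {1: 6}

    def test_diagonal_touch_depends_on_connectivity(self):
        mask = np.zeros((2, 2), bool)
        mask[0, 0] = mask[1, 1] = True
        _, sizes4 = label_clusters(mask, 4)
        _, sizes8 = label_clusters(mask, 8)
        assert sorted(sizes4.values()) == [1, 1]
        assert sorted(sizes8.values()) == [2]

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_random_masks_match_flood_fill_oracle(self, connectivity, rng):
        for _ in range(50):
            mask = rng.uniform(size=(8, 8)) < 0.4
            labels, sizes = label_clusters(mask, connectivity)
            comps = flood_fill_components(mask, connectivity)
            assert sorted(sizes.values()) == sorted(len(c) for c in comps)
            for comp in comps:  # every component maps to exactly one label
                ids = {labels[c] for c in comp}
                assert len(ids) == 1 and 0 not in ids

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(mask=hnp.arrays(bool, hnp.array_shapes(min_dims=2, max_dims=2,
                                                  min_side=1, max_side=7)),
           connectivity=st.sampled_from([4, 8]))
    def test_labelling_matches_flood_fill_for_arbitrary_masks(
            self, mask, connectivity):
        labels, sizes = label_clusters(mask, connectivity)
        comps = flood_fill_components(mask, connectivity)
        assert sorted(sizes.values()) == sorted(len(c) for c in comps)
        assert (labels > 0).sum() == mask.sum()

    def test_label_ids_in_scan_order(self):
        mask = np.zeros((3, 5), bool)
        mask[0, 4] = True   # first in raster order
        mask[2, 0] = True
        labels, _ = label_clusters(mask, 4)
        assert labels[0, 4] == 1 and labels[2, 0] == 2


class TestClusterNull:
    def test_empty_and_full_fill_degenerate(self):
        null0 = cluster_null((4, 4), 0.0, 4, 100, seed=0)
        assert null0.probabilities[0] == 1.0
        null1 = cluster_null((4, 4), 1.0, 4, 100, seed=0)
        assert null1.probabilities[16] == 1.0

    def test_exact_two_by_two_enumeration(self):
        # 2 tiles on a 2x2 grid: 6 placements, 4 edge-adjacent
        null = cluster_null((2, 2), 0.5, 4, exact=True)
        assert null.probabilities[2] == pytest.approx(4.0 / 6.0)
        assert null.probabilities[1] == pytest.approx(2.0 / 6.0)
        null8 = cluster_null((2, 2), 0.5, 8, exact=True)
        assert null8.probabilities[2] == pytest.approx(1.0)

    def test_monte_carlo_within_binomial_ci_of_exact(self):
        n_sim = 4000
        null = cluster_null((2, 2), 0.5, 4, n_sim, seed=5)
        p = 4.0 / 6.0
        ci = 2.576 * np.sqrt(p * (1 - p) / n_sim)
        assert abs(null.probabilities[2] - p) < ci

    @pytest.mark.parametrize("shape", [(1, 3), (2, 2), (3, 3)])
    def test_exact_mode_matches_independent_enumeration(self, shape):
        n_tiles = int(np.prod(shape))
        for n_fill in range(n_tiles + 1):
            null = cluster_null(shape, n_fill / n_tiles, 4, exact=True)
            expected = exact_max_cluster_distribution(shape, n_fill, 4)
            np.testing.assert_allclose(null.probabilities, expected,
                                       atol=1e-12)

    def test_seeded_reproducibility(self):
        a = cluster_null((6, 6), 0.2, 4, 300, seed=9)
        b = cluster_null((6, 6), 0.2, 4, 300, seed=9)
        np.testing.assert_array_equal(a.probabilities, b.probabilities)


class TestMinClusterSize:
    def test_no_tiles_possible_gives_one(self):
        null = cluster_null((3, 3), 0.0, 4, 100, seed=0)
        assert min_cluster_size(null, alpha=0.05, n_analyses=1) == 1

    def test_point_mass_distribution_tail_scan(self):
        from oscbeam.tilestats import ClusterNullDistribution
        probs = np.zeros(26)
        probs[10] = 1.0
        null = ClusterNullDistribution(grid_shape=(5, 5), fill_rate=0.4,
                                       connectivity=4, n_simulations=1000,
                                       probabilities=probs, seed=0)
        assert min_cluster_size(null, alpha=1e-6, n_analyses=1) == 11

    def test_monotone_in_alpha(self):
        null = cluster_null((10, 10), 0.2, 4, 2000, seed=3)
        k_strict = min_cluster_size(null, alpha=0.01)
        k_loose = min_cluster_size(null, alpha=0.10)
        assert k_strict >= k_loose


class TestApplyThreshold:
    def test_all_clusters_large_enough_is_identity(self):
        mask = np.zeros((2, 8), bool)
        mask[0, :6] = True
        labels, _ = label_clusters(mask, 4)
        out = apply_cluster_threshold(mask, labels, 6)
        np.testing.assert_array_equal(out.retained, mask)
        assert not out.dashed.any()

    def test_subthreshold_cluster_becomes_dashed(self):
        mask = np.zeros((2, 8), bool)
        mask[0, :5] = True
        labels, _ = label_clusters(mask, 4)
        out = apply_cluster_threshold(mask, labels, 6)
        assert not out.retained.any()
        np.testing.assert_array_equal(out.dashed, mask)

    def test_random_masks_match_bruteforce_filter(self, rng):
        for _ in range(20):
            mask = rng.uniform(size=(6, 6)) < 0.35
            labels, sizes = label_clusters(mask, 4)
            k_min = 3
            out = apply_cluster_threshold(mask, labels, k_min)
            comps = flood_fill_components(mask, 4)
            expected = np.zeros_like(mask)
            for comp in comps:
                if len(comp) >= k_min:
                    for c in comp:
                        expected[c] = True
            np.testing.assert_array_equal(out.retained, expected)


class TestCalibration:
    """Error control and power of the full tile decision chain on
    synthetic grids with independent tile noise."""

    @staticmethod
    def _decide(grids_a, grids_b, seed):
        res = tile_condition_test(grids_a, grids_b)
        mask = dual_criteria_mask(res)
        labels, _ = label_clusters(mask, 4)
        null = cluster_null(mask.shape, float(mask.mean()), 4,
                            n_simulations=500, seed=seed)
        k = min_cluster_size(null, alpha=0.05, n_analyses=12)
        return apply_cluster_threshold(mask, labels, k)

    def test_global_null_cohort_false_alarm_rate(self):
        rng = np.random.default_rng(41)
        hits = 0
        n_cohorts = 200
        for c in range(n_cohorts):
            a = rng.standard_normal((12, 20, 15))
            b = rng.standard_normal((12, 20, 15))
            hits += bool(self._decide(a, b, seed=c).retained.any())
        # <= alpha plus 99% Monte-Carlo margin
        assert hits / n_cohorts <= 0.05 + 2.576 * np.sqrt(
            0.05 * 0.95 / n_cohorts)

    def test_one_sd_block_effect_sensitivity(self):
        # A - B effect of 1 within-participant SD (of the paired
        # difference) over a 10-tile block, n = 19
        rng = np.random.default_rng(43)
        effect = np.zeros((20, 15))
        effect[5:10, 6:8] = 1.0
        noise_sd = 1.0 / np.sqrt(2.0)   # difference SD = 1
        sens = []
        for c in range(20):
            a = noise_sd * rng.standard_normal((19, 20, 15)) + effect
            b = noise_sd * rng.standard_normal((19, 20, 15))
            retained = self._decide(a, b, seed=1000 + c).retained
            sens.append((retained & (effect > 0)).sum() / 10.0)
        assert np.mean(sens) >= 0.8


class TestBehaviour:
    MEANS = {"taxonomic": (950.0, 0.87), "thematic_strong": (880.0, 0.95),
             "thematic_weak": (945.0, 0.88)}

    def _table(self, accuracies):
        rows = []
        for p, acc in enumerate(accuracies):
            for cond in self.MEANS:
                rows.append({"participant": f"sub-{p + 1:02d}",
                             "condition": cond, "rt_ms": 900.0 + p,
                             "accuracy": acc, "n_catch": 29})
        return pd.DataFrame(rows)

    def test_exclusion_rule_is_strict_below(self):
        table = self._table([0.74, 0.75, 0.9, 0.9])
        res = behavioural_tests(table)
        assert res["excluded"] == ["sub-01"]
        assert res["n_retained"] == 3

    def test_identical_columns_give_null_t(self):
        table = self._table([0.9] * 5)
        res = behavioural_tests(table)
        rt = res["report"][res["report"].measure == "reaction_time"]
        assert np.allclose(rt.t, 0.0)
        assert np.allclose(rt.p, 1.0)

    def test_nineteen_retained_gives_df_18(self):
        table = simulate_behaviour(20, self.MEANS, seed=2,
                                   poor_performer_indices=(7,))
        res = behavioural_tests(table)
        assert res["n_retained"] == 19
        assert (res["report"].df == 18).all()

    def test_all_excluded_rejected(self):
        table = self._table([0.5, 0.5, 0.5])
        with pytest.raises(ValueError, match="retained"):
            behavioural_tests(table)
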