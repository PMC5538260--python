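"""FBC profiles, sliding-window AFBC, RFBC scores, and thresholding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from conftest import brute_force_fbc, brute_force_rfbc
from fbctract.fbc_core import (
    FBCProfile,
    afbc_bundle,
    afbc_window,
    compute_fbc,
    rfbc,
    threshold,
    window_points,
)
from fbctract.se3_kernel import KernelTable
from fbctract.tract_model import Bundle


def _toy_bundle(seed=11):
    """3 streamlines x 5 points with hand-written, gently curved coordinates."""
    rng = np.random.default_rng(seed)
    base = np.column_stack([np.arange(5) * 0.2, np.zeros(5), np.zeros(5)])
    bend = np.column_stack([np.zeros(5), (np.arange(5) * 0.2) ** 2 * 0.1, np.zeros(5)])
    sls = [
        base + bend,
        base + [0.0, 0.8, 0.0],
        base + [0.0, 0.3, 0.9] - bend,
    ]
    sls = [s + rng.normal(0, 0.01, s.shape) for s in sls]
    return Bundle(sls)


class TestComputeFbc:
    def test_single_streamline_scores_zero(self, params):
        b = Bundle([np.column_stack([np.arange(10) * 0.2, np.zeros(10), np.zeros(10)])])
        prof = compute_fbc(b, params)
        assert np.all(prof.values[0] == 0)

    def test_two_parallel_streamlines_symmetry_and_edge_decay(self, params):
        pts = np.column_stack([np.arange(40) * 0.2, np.zeros(40), np.zeros(40)])
        b = Bundle([pts, pts + [0.0, 1.0, 0.0]])
        prof = compute_fbc(b, params)
        assert np.allclose(prof.values[0], prof.values[1], rtol=1e-12)
        interior = prof.values[0][15:25].min()
        assert interior > prof.values[0][0]
        assert interior > prof.values[0][-1]

    def test_matches_brute_force_no_cutoff(self, params):
        b = _toy_bundle()
        oracle = brute_force_fbc(b, params, cutoff=None)
        got = compute_fbc(b, params, cutoff=1e6)
        for o, g in zip(oracle, got.values):
            assert np.max(np.abs(o - g) / o) < 1e-10

    def test_matches_brute_force_with_cutoff(self, params):
        rng = np.random.default_rng(3)
        sls = []
        for i in range(6):
            start = rng.uniform(-3, 3, 3)
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            sls.append(start + np.outer(np.arange(12) * 0.4, d))
        b = Bundle(sls)
        oracle = brute_force_fbc(b, params, cutoff=6.0)
        got = compute_fbc(b, params, cutoff=6.0)
        ref = np.concatenate(oracle)
        val = np.concatenate(got.values)
        big = ref > 0
        assert np.max(np.abs(ref[big] - val[big]) / ref[big]) < 1e-10

    def test_lookup_table_exact_on_lattice_bundle(self, params, kernel_table,
                                                  toy_lattice_bundle):
        direct = compute_fbc(toy_lattice_bundle, params, cutoff=6.0)
        via_table = compute_fbc(toy_lattice_bundle, kernel_table, cutoff=6.0)
        d = np.concatenate(direct.values)
        t = np.concatenate(via_table.values)
        assert np.max(np.abs(d - t) / d) < 1e-9

    def test_cutoff_larger_than_table_rejected(self, kernel_table):
        b = _toy_bundle()
        with pytest.raises(ValueError, match="half-width"):
            compute_fbc(b, kernel_table, cutoff=10.0)

    def test_profile_rejects_negative_values(self):
        with pytest.raises(ValueError):
            FBCProfile(indices=np.array([0]), values=[np.array([1.0, -0.1])])


class TestAfbcWindow:
    def test_window_point_count_at_default_step(self):
        assert window_points(2.0, 0.2) == 10

    def test_constant_profile_returns_constant(self):
        assert afbc_window(np.full(50, 3.25), 2.0, 0.2) == pytest.approx(3.25)

    def test_minimum_window_mean_forced_by_definition(self):
        assert afbc_window(np.array([1.0, 2, 3, 4, 5]), 0.4, 0.2) == pytest.approx(1.5)

    def test_short_profile_falls_back_to_whole_mean(self):
        assert afbc_window(np.array([2.0, 4.0]), 2.0, 0.2) == pytest.approx(3.0)

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            afbc_window(np.array([]), 2.0, 0.2)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 100), min_size=1, max_size=60), st.integers(1, 12))
    def test_matches_naive_window_scan(self, vals, wp):
        prof = np.asarray(vals)
        got = afbc_window(prof, alpha=wp * 0.2, step=0.2)
        if len(prof) <= wp:
            expected = prof.mean()
        else:
            expected = min(prof[i:i + wp].mean() for i in range(len(prof) - wp + 1))
        assert got == pytest.approx(expected, abs=1e-9)


class TestAfbcBundle:
    def test_equal_length_profiles_average(self):
        prof = FBCProfile(np.array([0, 1]), [np.full(4, 2.0), np.full(4, 4.0)])
        assert afbc_bundle(prof) == pytest.approx(3.0)

    def test_point_weighted_pooling_convention(self):
        prof = FBCProfile(np.array([0, 1]), [np.ones(4), np.full(2, 3.0)])
        assert afbc_bundle(prof) == pytest.approx(5.0 / 3.0)

    def test_degenerate_all_zero_rejected(self):
        prof = FBCProfile(np.array([0]), [np.zeros(5)])
        with pytest.raises(ValueError, match="RFBC undefined"):
            afbc_bundle(prof)


class TestRfbc:
    def test_scores_consistent_with_brute_force(self, params):
        b = _toy_bundle()
        _, oracle_afbc, oracle_rfbc = brute_force_rfbc(b, params, alpha=0.4, step=0.2)
        got = rfbc(b, params, alpha=0.4, step=0.2, cutoff=1e6)
        assert np.max(np.abs(got.afbc_alpha - oracle_afbc) / oracle_afbc) < 1e-10
        assert np.max(np.abs(got.rfbc - oracle_rfbc) / oracle_rfbc) < 1e-10

    def test_ratio_identity_and_window_bound(self, standard_scores):
        s = standard_scores
        assert np.allclose(s.rfbc, s.afbc_alpha / s.bundle_afbc, rtol=0, atol=0)
        assert s.window_points == 10

    def test_kernel_scale_invariance(self, params, kernel_table, toy_lattice_bundle):
        base = rfbc(toy_lattice_bundle, kernel_table, alpha=1.0, step=0.5)
        scaled_table = KernelTable(
            kernel_table.params, kernel_table.half_width, kernel_table.spacing,
            kernel_table.dirs, kernel_table.values * 10.0,
        )
        scaled = rfbc(toy_lattice_bundle, scaled_table, alpha=1.0, step=0.5)
        assert np.allclose(base.rfbc, scaled.rfbc, rtol=1e-12)

    def test_planted_orthogonal_outlier_scores_lowest(self, params):
        rng = np.random.default_rng(21)
        n_pts = 21
        coherent = [
            np.column_stack([np.arange(n_pts) * 0.5, np.zeros(n_pts), np.zeros(n_pts)])
            + rng.normal(0, 0.4, 3)
            for _ in range(30)
        ]
        outlier = np.column_stack(
            [np.full(n_pts, 5.0), np.full(n_pts, 5.0), np.arange(n_pts) * 0.5 - 5.0]
        )
        b = Bundle(coherent + [outlier])
        scores = rfbc(b, params, alpha=2.0, step=0.5)
        assert np.argmin(scores.rfbc) == 30
        assert scores.rfbc[30] < 0.5 * scores.rfbc[:30].min()
        # cross-check the full pipeline against the literal brute-force sums;
        # the comparison is on non-negligible scores (the outlier's ~1e-32
        # score is pure accumulation-order noise at relative precision)
        _, _, oracle = brute_force_rfbc(b, params, alpha=2.0, step=0.5, cutoff=6.0)
        good = oracle > 1e-6 * oracle.max()
        assert np.max(np.abs(scores.rfbc[good] - oracle[good]) / oracle[good]) < 1e-10
        assert scores.rfbc[30] == pytest.approx(oracle[30], rel=1e-6)

    def test_subsampled_sources_leave_rfbc_stable(self, params, standard_fixture,
                                                  standard_scores):
        sub = rfbc(standard_fixture, params, subsample=2)
        base = standard_scores.rfbc
        big = base > 0.01
        assert np.max(np.abs(sub.rfbc[big] - base[big]) / base[big]) < 0.05


class TestInvariances:
    def test_rigid_motion_invariance(self, params):
        b = _toy_bundle()
        base = rfbc(b, params, alpha=0.4, step=0.2)
        rot = Rotation.from_euler("xyz", [20, -35, 60], degrees=True).as_matrix()
        shift = np.array([5.0, -3.0, 12.0])
        moved = Bundle([s.points @ rot.T + shift for s in b])
        got = rfbc(moved, params, alpha=0.4, step=0.2)
        assert np.max(np.abs(got.rfbc - base.rfbc) / base.rfbc) < 1e-6

    def test_streamline_reversal_invariance(self, params):
        b = _toy_bundle()
        base = rfbc(b, params, alpha=0.4, step=0.2)
        flipped = Bundle([b.streamlines[0].points[::-1].copy()]
                         + [s.points for s in b.streamlines[1:]])
        got = rfbc(flipped, params, alpha=0.4, step=0.2)
        assert np.max(np.abs(got.rfbc - base.rfbc)) < 1e-9 * base.rfbc.max()

    def test_permutation_equivariance(self, params):
        b = _toy_bundle()
        base = rfbc(b, params, alpha=0.4, step=0.2)
        perm = [2, 0, 1]
        permuted = Bundle([b.streamlines[i].points for i in perm])
        got = rfbc(permuted, params, alpha=0.4, step=0.2)
        assert np.allclose(got.rfbc, base.rfbc[perm], rtol=1e-12)


class TestThreshold:
    def test_zero_epsilon_retains_all(self, standard_fixture, standard_scores):
        assert len(threshold(standard_fixture, standard_scores, 0.0)) == len(standard_fixture)

    def test_above_max_empties_bundle(self, standard_fixture, standard_scores):
        eps_max = standard_scores.rfbc.max() + 1e-9
        assert len(threshold(standard_fixture, standard_scores, eps_max)) == 0

    def test_midway_epsilon_removes_exactly_planted(self, standard_fixture, standard_scores):
        lab = standard_fixture.labels
        worst_clean = standard_scores.rfbc[lab == "clean"].min()
        best_planted = standard_scores.rfbc[lab == "spurious"].max()
        eps = 0.5 * (worst_clean + best_planted)
        kept = threshold(standard_fixture, standard_scores, eps)
        assert np.all(kept.labels == "clean")
        assert len(kept) == np.sum(lab == "clean")

    def test_subset_monotone_in_epsilon(self, standard_fixture, standard_scores):
        grids = np.linspace(0, standard_scores.rfbc.max() * 1.01, 15)
        prev = None
        for eps in grids:
            kept = set(threshold(standard_fixture, standard_scores, eps).indices)
            if prev is not None:
                assert kept.issubset(prev)
            prev = kept

    def test_scores_from_other_bundle_rejected(self, standard_fixture, standard_scores):
        sub = standard_fixture.subset(np.arange(len(standard_fixture)) < 5)
        with pytest.raises(ValueError, match="not computed on this bundle"):
            threshold(sub, standard_scores, 0.1)
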