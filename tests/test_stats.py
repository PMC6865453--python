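"""Flanker quantification, correlation maps, cluster permutation, median split."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import alphatune as at


def _trials(con_rts, inc_rts, correct=None):
    rts = list(con_rts) + list(inc_rts)
    congr = ["congruent"] * len(con_rts) + ["incongruent"] * len(inc_rts)
    return pd.DataFrame(
        {
            "congruency": congr,
            "rt_ms": rts,
            "correct": correct if correct is not None else [True] * len(rts),
        }
    )


class TestFlankerEffect:
    def test_arithmetic(self):
        fx = at.flanker_effect(_trials([400, 400], [450, 450]))
        assert fx.delta_rt_ms == pytest.approx(50.0)

    def test_identical_distributions_give_zero(self):
        fx = at.flanker_effect(_trials([400, 410, 420], [400, 410, 420]))
        assert fx.delta_rt_ms == pytest.approx(0.0)
        assert fx.cohens_d == pytest.approx(0.0)

    def test_sign_consistency_and_pooled_sd(self):
        con = [400.0, 420.0, 440.0]
        inc = [460.0, 480.0, 500.0]
        fx = at.flanker_effect(_trials(con, inc))
        pooled = np.sqrt((np.var(con, ddof=1) + np.var(inc, ddof=1)) / 2)
        assert fx.cohens_d == pytest.approx(60.0 / pooled)
        assert np.sign(fx.cohens_d) == np.sign(fx.delta_rt_ms)

    def test_incorrect_trials_excluded(self):
        df = _trials([400, 400, 999], [450, 450, 999], correct=[True] * 2 + [False] + [True] * 2 + [False])
        assert at.flanker_effect(df).delta_rt_ms == pytest.approx(50.0)

    def test_missing_condition_raises(self):
        with pytest.raises(ValueError):
            at.flanker_effect(_trials([400], []))

    def test_recovers_generative_cost(self, truth32):
        design = at.make_design(100, 16, seed=1)
        truth = at.GroundTruth(
            mixing=truth32.mixing, flanker_base_cost_ms=60.0,
            flanker_depth_slope_ms=-50.0, rt_noise_sd_ms=30.0,
        )
        df = at.simulate_behavior(design, truth, 0.5, np.random.default_rng(2))
        fx = at.flanker_effect(df)
        se = 30.0 * np.sqrt(1 / fx.n_congruent + 1 / fx.n_incongruent)
        assert abs(fx.delta_rt_ms - 35.0) < 2 * se  # 60 - 50*0.5


class TestSpearmanMap:
    def test_monotone_transform_gives_unit_rho(self):
        rng = np.random.default_rng(0)
        tuning = rng.normal(size=(10, 3, 4))
        behavior = np.exp(tuning[:, 1, 2])  # monotone in one cell
        rho = at.spearman_map(tuning, behavior)
        assert rho[1, 2] == pytest.approx(1.0)

    def test_matches_scipy_per_cell(self):
        rng = np.random.default_rng(1)
        tuning = rng.normal(size=(12, 2, 3))
        behavior = rng.normal(size=12)
        rho = at.spearman_map(tuning, behavior)
        for i in range(2):
            for j in range(3):
                ref = sps.spearmanr(tuning[:, i, j], behavior).statistic
                assert rho[i, j] == pytest.approx(ref, abs=1e-12)

    def test_independent_behavior_mean_rho_near_zero(self):
        rng = np.random.default_rng(2)
        rhos = [
            at.spearman_map(rng.normal(size=(15, 4, 8)), rng.normal(size=15)).mean()
            for _ in range(200)
        ]
        assert abs(np.mean(rhos)) < 3 * np.std(rhos) / np.sqrt(len(rhos))

    def test_constant_cell_emits_zero_with_warning(self):
        tuning = np.random.default_rng(3).normal(size=(8, 2))
        tuning[:, 0] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            rho = at.spearman_map(tuning, np.arange(8.0))
        assert rho[0] == 0.0

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            at.spearman_map(np.ones((3, 2)), np.ones(3))


class TestClusterPermutation:
    def test_planted_effect_hits_p_floor(self):
        rng = np.random.default_rng(4)
        maps = rng.normal(size=(20, 10, 8))
        maps[:, 3:6, 2:4] += 2.0
        res = at.cluster_permutation(maps, n_perm=500, seed=0)
        top = res.clusters[0]
        assert top.p_value == pytest.approx(1.0 / 501.0)
        cells = {tuple(c) for c in top.cells.tolist()}
        assert {(t, o) for t in range(3, 6) for o in (2, 3)} <= cells

    def test_two_sided_sign_invariance(self):
        rng = np.random.default_rng(5)
        maps = rng.normal(size=(15, 6, 8))
        maps[:, 1:3, 4:6] -= 1.5
        a = at.cluster_permutation(maps, n_perm=300, seed=9)
        b = at.cluster_permutation(-maps, n_perm=300, seed=9)
        assert a.min_p() == pytest.approx(b.min_p())
        np.testing.assert_allclose(
            sorted(abs(c.mass) for c in a.clusters),
            sorted(abs(c.mass) for c in b.clusters),
        )

    def test_identical_maps_sit_at_null_extreme(self):
        one = np.random.default_rng(6).normal(size=(4, 8)) * 0 + 1.0
        maps = np.tile(one, (12, 1, 1))
        res = at.cluster_permutation(maps, n_perm=400, seed=1)
        assert res.min_p() == pytest.approx(1.0 / 401.0)

    def test_circular_wrap_yields_single_cluster(self):
        """A planted effect spanning the ±180° edge must not split in two."""
        rng = np.random.default_rng(7)
        maps = rng.normal(size=(20, 5, 8)) * 0.5
        maps[:, 2, [0, 1, 7]] += 3.0  # offsets -180°, -135°, +135°: contiguous circularly
        res = at.cluster_permutation(maps, n_perm=200, seed=2)
        top = res.clusters[0]
        cols = set(top.cells[:, 1].tolist())
        assert {0, 1, 7} <= cols

    def test_subthreshold_map_returns_empty_cluster_list(self):
        # perfectly antisymmetric subject pairs: t = 0 in every cell
        pattern = np.random.default_rng(8).normal(size=(4, 8))
        maps = np.stack([pattern if i % 2 else -pattern for i in range(10)])
        res = at.cluster_permutation(maps, n_perm=200, seed=3)
        assert res.clusters == []
        assert res.min_p() == 1.0

    def test_low_permutation_count_warns(self):
        maps = np.random.default_rng(10).normal(size=(8, 3, 8))
        with pytest.warns(UserWarning, match="resolution"):
            at.cluster_permutation(maps, n_perm=50, seed=0)

    def test_correlation_mode_finds_linked_cells(self):
        rng = np.random.default_rng(11)
        behavior = rng.normal(size=24)
        maps = rng.normal(size=(24, 6, 8)) * 0.5
        maps[:, 4, 3] -= 2.0 * behavior
        res = at.cluster_permutation(maps, behavior=behavior, n_perm=400, seed=5)
        top = res.clusters[0]
        assert top.mass < 0
        assert (4, 3) in {tuple(c) for c in top.cells.tolist()}
        assert top.p_value < 0.05

    def test_matches_mne_observed_clusters(self):
        """Cross-check cluster formation and masses against MNE-Python."""
        mne = pytest.importorskip("mne")
        from scipy.sparse import lil_matrix

        rng = np.random.default_rng(12)
        T, O = 6, 8
        maps = rng.normal(size=(14, T, O))
        maps[:, 1:3, 0:2] += 1.4
        S = maps.shape[0]
        thr = sps.t.ppf(1 - 0.025, df=S - 1)

        adj = lil_matrix((T * O, T * O), dtype=bool)
        for t in range(T):
            for o in range(O):
                i = t * O + o
                if t + 1 < T:
                    adj[i, (t + 1) * O + o] = True
                adj[i, t * O + (o + 1) % O] = True
        adj = (adj + adj.T).tocsr()

        t_obs, clusters, _, _ = mne.stats.permutation_cluster_1samp_test(
            maps.reshape(S, T * O), threshold=thr, n_permutations=100,
            adjacency=adj, tail=0, seed=0, out_type="indices", verbose="error",
        )
        mine = at.cluster_permutation(maps, n_perm=100, cell_alpha=0.05, seed=0)
        ref = sorted(
            round(float(t_obs[c[0]].sum()), 6) for c in clusters
        )
        got = sorted(round(c.mass, 6) for c in mine.clusters)
        assert got == ref


class TestMedianSplit:
    def _decoded(self, design, seed=0):
        rng = np.random.default_rng(seed)
        resp = rng.normal(size=(8, len(design), 3))
        folds = np.zeros(len(design), dtype=int)
        return at.DecodeResult(resp, folds)

    def test_partition_within_each_location(self, basis):
        design = at.make_design(10, 16, seed=1)
        design["rt_ms"] = np.random.default_rng(2).normal(500, 40, len(design))
        res = self._decoded(design)
        slow, fast = at.median_split_tuning(res, design, basis)
        assert slow.n_trials + fast.n_trials == len(design)
        assert slow.n_trials == fast.n_trials  # even count per location

    def test_all_ties_split_into_equal_halves(self, basis):
        design = at.make_design(8, 16, seed=3)
        design["rt_ms"] = 500.0
        slow, fast = at.median_split_tuning(self._decoded(design), design, basis)
        assert slow.n_trials == fast.n_trials == len(design) // 2

    def test_odd_counts_put_extra_trial_in_slow_group(self, basis):
        design = at.make_design(9, 16, seed=4)  # odd count: extra trial goes slow
        rng = np.random.default_rng(5)
        design["rt_ms"] = rng.normal(500, 50, len(design))
        slow, fast = at.median_split_tuning(self._decoded(design), design, basis)
        assert slow.n_trials == fast.n_trials + 16

    def test_fast_trials_keep_late_tuning(self, basis):
        """Generative dropout on slow trials: fast curve exceeds slow late in delay."""
        cohort = at.simulate_cohort(
            1, seed=6, n_trials_per_location=20, n_sensors=16,
            time_bins=np.array([-0.75, -0.25]), sustain_link=True,
            depth_range=(0.6, 0.6),
        )
        s = cohort[0]
        res = at.crossval_decode(s.power.power[:, :, 0, :], s.trials, basis, k=5, seed=0)
        slow, fast = at.median_split_tuning(res, s.trials, basis)
        mag_fast = at.tuning_magnitude(fast)
        mag_slow = at.tuning_magnitude(slow)
        assert mag_fast[1] > mag_slow[1]  # late bin
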