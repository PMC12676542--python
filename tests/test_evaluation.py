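import numpy as np
import pytest
from scipy import stats

import epiparc as ep
from epiparc.cohort import RunTimeSeries, StimulationDesign, make_alternating_design
from epiparc.evaluation import (bh_fdr, compare_approaches, dvars,
                                loro_evaluate, resting_homogeneity, stim_glm,
                                task_inhomogeneity)
from epiparc.hrf import stim_regressor


def _run(vertex_ts, roi=None, tr=2.0):
    vertex_ts = np.asarray(vertex_ts, float)
    if roi is None:
        roi = vertex_ts[:, :1].copy()
    return RunTimeSeries(subject_id=0, session_id=0, tr_seconds=tr,
                         vertex_ts=vertex_ts, roi_ts=np.asarray(roi, float))


# --------------------------------------------------------------- homogeneity

class TestRestingHomogeneity:
    def test_identical_members_score_one(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal((40, 1))
        vts = np.repeat(base, 6, axis=1)
        res = resting_homogeneity(np.ones(6, int), _run(vts), K=1)
        assert res.value == pytest.approx(1.0)

    def test_hand_weighted_average(self):
        """Two networks of sizes 3 and 1: value = (3*h1 + 1*1)/4 where the
        singleton scores 1 and h1 is computed by a naive loop oracle."""
        rng = np.random.default_rng(1)
        shared = rng.standard_normal(50)
        vts = np.column_stack([shared + 0.8 * rng.standard_normal(50)
                               for _ in range(3)]
                              + [rng.standard_normal(50)])
        labels = np.array([1, 1, 1, 2])
        res = resting_homogeneity(labels, _run(vts), K=2)
        member = vts[:, :3]
        mean_ts = member.mean(axis=1)
        h1 = np.mean([np.corrcoef(member[:, j], mean_ts)[0, 1]
                      for j in range(3)])
        assert res.per_network[0] == pytest.approx(h1)
        assert res.per_network[1] == pytest.approx(1.0)
        assert res.value == pytest.approx((3 * h1 + 1 * 1.0) / 4)

    def test_matches_naive_loop_oracle(self, tiny_cohort):
        graph, truth, runs = tiny_cohort
        run = runs[(0, 0)]
        labels = truth.subject_labels[0]
        res = resting_homogeneity(labels, run, K=3)
        per, sizes = [], []
        for k in (1, 2, 3):
            cols = run.vertex_ts[:, labels == k]
            sizes.append(cols.shape[1])
            m = cols.mean(axis=1)
            per.append(np.mean([np.corrcoef(cols[:, j], m)[0, 1]
                                for j in range(cols.shape[1])]))
        expected = np.dot(per, sizes) / np.sum(sizes)
        assert res.value == pytest.approx(expected, abs=1e-12)

    def test_empty_network_warned_and_excluded(self):
        rng = np.random.default_rng(2)
        vts = rng.standard_normal((30, 4))
        with pytest.warns(UserWarning, match="empty"):
            res = resting_homogeneity(np.array([1, 1, 1, 1]), _run(vts), K=2)
        assert np.isnan(res.per_network[1])
        assert np.isfinite(res.value)


# ----------------------------------------------------------------- stim GLM

class TestStimGLM:
    def test_perfect_regressor_recovers_beta(self):
        design = make_alternating_design(6, 15)
        T = design.n_frames
        reg = stim_regressor(T, design.block_onsets, design.block_durations,
                             design.block_kinds, 2.0)
        vts = np.column_stack([0.5 + 3.0 * reg + 1e-6 * np.sin(np.arange(T)),
                               np.random.default_rng(0).standard_normal(T)])
        zmap = stim_glm(_run(vts), design)
        assert zmap.z[0] > 1e4          # essentially noiseless fit
        assert abs(zmap.z[1]) < 5

    def test_null_z_standard_normal(self):
        """With pure noise the z map over many vertices has mean ~0, SD ~1."""
        design = make_alternating_design(8, 15)
        rng = np.random.default_rng(3)
        vts = rng.standard_normal((design.n_frames, 3000))
        z = stim_glm(_run(vts), design).z
        assert abs(np.mean(z)) < 0.05
        assert np.std(z) == pytest.approx(1.0, abs=0.05)

    def test_type_one_error_near_nominal(self):
        """Fraction of null vertices with |z| above the normal 0.975 quantile
        is ~5% (3000 vertices; binomial 3 SD band)."""
        design = make_alternating_design(8, 15)
        rng = np.random.default_rng(4)
        vts = rng.standard_normal((design.n_frames, 3000))
        z = stim_glm(_run(vts), design).z
        frac = np.mean(np.abs(z) > stats.norm.ppf(0.975))
        se = np.sqrt(0.05 * 0.95 / 3000)
        assert abs(frac - 0.05) < 3 * se + 0.01

    def test_constant_regressor_rejected(self):
        design = StimulationDesign([0], [40], ["rest"])
        vts = np.random.default_rng(5).standard_normal((40, 3))
        with pytest.raises(ValueError, match="collinear"):
            stim_glm(_run(vts), design)


class TestTaskInhomogeneity:
    def test_constant_z_within_network_scores_zero(self):
        zmap = ep.ActivationZMap(0, np.array([2.0, 2.0, 2.0, -1.0, -1.0]))
        res = task_inhomogeneity(np.array([1, 1, 1, 2, 2]), zmap, K=2)
        assert res.value == pytest.approx(0.0)

    def test_hand_example_sqrt_two(self):
        """z = (0, 2) in one network: sample SD (ddof=1) is sqrt(2)."""
        zmap = ep.ActivationZMap(0, np.array([0.0, 2.0]))
        res = task_inhomogeneity(np.array([1, 1]), zmap, K=1)
        assert res.value == pytest.approx(np.sqrt(2))

    def test_singleton_scores_zero_with_warning(self):
        zmap = ep.ActivationZMap(0, np.array([1.0, 3.0, 5.0]))
        with pytest.warns(UserWarning, match="singleton"):
            res = task_inhomogeneity(np.array([1, 2, 2]), zmap, K=2)
        assert res.per_network[0] == pytest.approx(0.0)

    def test_matches_numpy_oracle(self):
        rng = np.random.default_rng(6)
        z = rng.standard_normal(60)
        labels = rng.integers(1, 4, 60)
        res = task_inhomogeneity(labels, ep.ActivationZMap(0, z), K=3)
        per = [np.std(z[labels == k], ddof=1) for k in (1, 2, 3)]
        sizes = [np.sum(labels == k) for k in (1, 2, 3)]
        assert res.value == pytest.approx(np.dot(per, sizes) / np.sum(sizes))


# --------------------------------------------------------------------- LORO

class TestLORO:
    def test_fixed_source_equals_plain_mean(self, tiny_cohort):
        """If the parcellation ignores the training runs, LORO reduces to the
        plain mean of the metric over runs."""
        graph, truth, runs = tiny_cohort
        rs = [runs[(2, t)] for t in range(2)]
        labels = truth.subject_labels[2]
        metric = lambda lab, run: resting_homogeneity(lab, run, 3).value
        mean, folds = loro_evaluate(rs, lambda train: labels, metric)
        assert len(folds) == 2
        assert mean == pytest.approx(np.mean([metric(labels, r) for r in rs]))

    def test_single_run_rejected(self, tiny_cohort):
        _, truth, runs = tiny_cohort
        with pytest.raises(ValueError):
            loro_evaluate([runs[(0, 0)]], lambda train: truth.subject_labels[0],
                          lambda lab, run: 0.0)

    def test_held_out_run_never_in_training_set(self, tiny_cohort):
        """Poison probe: the source fails loudly if it ever receives the
        held-out run."""
        _, truth, runs = tiny_cohort
        rs = [runs[(1, t)] for t in range(2)]
        seen = []

        def source(train):
            assert len(train) == 1
            seen.append(train[0].session_id)
            return truth.subject_labels[1]

        loro_evaluate(rs, source, lambda lab, run: float(run.session_id))
        assert seen == [1, 0]  # fold t trains on the other session


# ------------------------------------------------------------- paired stats

class TestCompareApproaches:
    def test_fifteen_pairs_for_six_approaches(self):
        rng = np.random.default_rng(7)
        vals = rng.standard_normal((12, 6))
        res = compare_approaches(vals, [f"a{i}" for i in range(6)])
        iu = np.triu_indices(6, 1)
        assert len(iu[0]) == 15
        assert np.all(np.isfinite(res.p[iu]))
        assert res.dof == 11
        assert np.allclose(res.t, -res.t.T, equal_nan=True)

    def test_matches_scipy_ttest_rel(self):
        rng = np.random.default_rng(8)
        vals = rng.standard_normal((10, 3)) + [0.0, 0.5, 1.0]
        res = compare_approaches(vals)
        for i in range(3):
            for j in range(i + 1, 3):
                ref = stats.ttest_rel(vals[:, i], vals[:, j])
                assert res.t[i, j] == pytest.approx(ref.statistic)
                assert res.p[i, j] == pytest.approx(ref.pvalue)

    def test_constant_shift_flagged_not_crashed(self):
        vals = np.column_stack([np.arange(8.0), np.arange(8.0) + 1.0])
        with pytest.warns(UserWarning, match="zero-variance"):
            res = compare_approaches(vals)
        assert np.isnan(res.p[0, 1])
        assert not res.significant[0, 1]

    def test_fdr_false_positive_rate_controlled_under_null(self):
        """Under a global null, the fraction of replicates with any q < 0.05
        across the 3 pairs stays near or below 5% (1000 replicates)."""
        rng = np.random.default_rng(9)
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            vals = rng.standard_normal((10, 3))
            res = compare_approaches(vals)
            iu = np.triu_indices(3, 1)
            hits += bool(np.any(res.q[iu] < 0.05))
        rate = hits / n_rep
        assert rate < 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)


class TestBHFDR:
    def test_hand_oracle(self):
        """p = [0.01, 0.02, 0.03, 0.5]: BH at q=0.05 rejects the first three
        (0.03 <= 3/4 * 0.05) and the adjusted q-values are
        [0.04, 0.04, 0.04, 0.5]."""
        rej, q = bh_fdr([0.01, 0.02, 0.03, 0.5], 0.05)
        assert rej.tolist() == [True, True, True, False]
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.5])

    def test_all_ones_nothing_rejected(self):
        rej, q = bh_fdr([1.0, 1.0, 1.0])
        assert not rej.any()
        assert np.allclose(q, 1.0)

    def test_single_p_passthrough(self):
        rej, q = bh_fdr([0.03])
        assert rej.tolist() == [True]
        assert q[0] == pytest.approx(0.03)

    def test_empty_and_nan(self):
        rej, q = bh_fdr([])
        assert rej.size == 0 and q.size == 0
        rej, q = bh_fdr([0.01, np.nan])
        assert not rej[1] and np.isnan(q[1])


class TestDVARS:
    def test_constant_series_zero(self):
        vts = np.ones((30, 5))
        assert dvars(_run(vts, roi=np.arange(30.0)[:, None])) == 0.0

    def test_alternating_steps_of_two(self):
        """Frames alternate between 0 and 2 everywhere: every backward
        difference is +-2, so DVARS = 2."""
        vts = np.tile(np.array([0.0, 2.0]), 15)[:, None] * np.ones((1, 4))
        assert dvars(_run(vts, roi=np.arange(30.0)[:, None])) == pytest.approx(2.0)

    def test_matches_formula(self):
        rng = np.random.default_rng(10)
        vts = rng.standard_normal((25, 7))
        expected = np.sqrt(np.mean(np.diff(vts, axis=0) ** 2))
        assert dvars(_run(vts, roi=np.arange(25.0)[:, None])) == pytest.approx(expected)
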