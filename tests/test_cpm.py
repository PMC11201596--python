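"""CPM: selection statistics, strengths, cross-validation, permutations."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import netfingerprint as nf
from netfingerprint import calibration as cal
from netfingerprint.errors import DataError, ParameterError


def _random_matrices(rng, n_subjects, n_nodes):
    a = rng.standard_normal((n_subjects, n_nodes, n_nodes))
    a = (a + a.transpose(0, 2, 1)) / 2
    for m in a:
        np.fill_diagonal(m, 1.0)
    return a


class TestEdgeBehaviorCorrelation:
    def test_behavior_equal_to_edge_gives_unit_correlation(self):
        rng = np.random.default_rng(0)
        mats = _random_matrices(rng, 25, 6)
        behavior = mats[:, 0, 1]
        stats_df = nf.edge_behavior_correlation(mats, behavior)
        row = stats_df[(stats_df["i"] == 0) & (stats_df["j"] == 1)].iloc[0]
        assert row["r"] == pytest.approx(1.0, abs=1e-12)
        assert row["p"] == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_covariates_leave_partial_equal_to_simple(self):
        rng = np.random.default_rng(1)
        n = 60
        mats = _random_matrices(rng, n, 5)
        behavior = rng.standard_normal(n)
        # covariates orthogonalized against behavior and every edge column
        iu = np.triu_indices(5, 1)
        edges = mats[:, iu[0], iu[1]]
        basis = np.column_stack([np.ones(n), behavior, edges])
        q, _ = np.linalg.qr(basis)
        raw = rng.standard_normal((n, 2))
        cov = raw - q @ (q.T @ raw)
        partial = nf.edge_behavior_correlation(mats, behavior, covariates=cov)
        simple = nf.edge_behavior_correlation(mats, behavior)
        assert np.allclose(partial["r"], simple["r"], atol=1e-10)

    def test_residualized_method_matches_two_stage_oracle(self):
        rng = np.random.default_rng(2)
        n = 40
        mats = _random_matrices(rng, n, 5)
        behavior = rng.standard_normal(n)
        cov = rng.standard_normal((n, 2))
        out = nf.edge_behavior_correlation(mats, behavior, cov, method="residualized")
        z = np.column_stack([np.ones(n), cov])
        resid = behavior - z @ np.linalg.lstsq(z, behavior, rcond=None)[0]
        iu = np.triu_indices(5, 1)
        for row, (i, j) in zip(out.itertuples(), zip(*iu)):
            ref = np.corrcoef(mats[:, i, j], resid)[0, 1]
            assert row.r == pytest.approx(ref, abs=1e-10)

    def test_null_p_values_calibrated(self):
        rng = np.random.default_rng(3)
        hits = total = 0
        for _ in range(200):
            mats = _random_matrices(rng, 50, 8)
            behavior = rng.standard_normal(50)
            out = nf.edge_behavior_correlation(mats, behavior)
            hits += int((out["p"] < 0.01).sum())
            total += len(out)
        assert hits / total == pytest.approx(0.01, abs=0.005)

    def test_constant_behavior_rejected(self):
        mats = _random_matrices(np.random.default_rng(4), 12, 4)
        with pytest.raises(DataError, match="constant"):
            nf.edge_behavior_correlation(mats, np.ones(12))

    def test_too_few_subjects_rejected(self):
        mats = _random_matrices(np.random.default_rng(5), 8, 4)
        with pytest.raises(DataError, match="10 subjects"):
            nf.edge_behavior_correlation(mats, np.arange(8.0))


class TestSelectEdges:
    def test_threshold_one_selects_everything_split_by_sign(self):
        rng = np.random.default_rng(6)
        mats = _random_matrices(rng, 20, 5)
        stats_df = nf.edge_behavior_correlation(mats, rng.standard_normal(20))
        mask = nf.select_edges(stats_df, p_threshold=1.0)
        assert mask.n_edges == len(stats_df)
        assert len(mask.positive) == int((stats_df["r"] > 0).sum())

    def test_planted_edges_recovered_with_signs(self):
        # 10 positive + 10 negative planted edges at a per-edge severity
        # correlation giving single-shot detection power ~0.95 at n=500
        n, frames, base = 500, 240, 0.2
        r_e = 0.19
        eff = cal.effect_for_edge_severity_r(r_e, base, frames)
        pos = tuple((0, i) for i in range(1, 11))
        neg = tuple((11 + i, 22 + i) for i in range(10))
        cfg = nf.SimulationConfig(
            n_subjects=n, n_nodes=33, frames_per_block=60,
            n_blocks_per_condition=4, planted_pos_edges=pos,
            planted_neg_edges=neg, effect_size=eff,
            conditions=("punishment",), seed=31,
        )
        _, cov, series, truth = nf.simulate_cohort(cfg)
        mats = np.asarray(
            [nf.connectivity_matrix(series["punishment"][i]).values for i in range(n)]
        )
        stats_df = nf.edge_behavior_correlation(mats, truth.latent_severity, cov)
        mask = nf.select_edges(stats_df, p_threshold=0.01)
        sens = (
            sum(e in mask.positive for e in pos) + sum(e in mask.negative for e in neg)
        ) / 20
        assert sens >= 0.85
        # no planted edge recovered with the wrong sign
        assert not (set(pos) & mask.negative) and not (set(neg) & mask.positive)

    def test_null_selection_count_near_alpha_times_edges(self, null_cohort):
        cfg, _, cov, mats, truth = null_cohort
        stats_df = nf.edge_behavior_correlation(mats, truth.latent_severity, cov)
        mask = nf.select_edges(stats_df, p_threshold=0.05)
        expected = 0.05 * len(stats_df)
        assert mask.n_edges <= expected + 3 * np.sqrt(expected) + 1

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ParameterError, match="p_threshold"):
            nf.select_edges(pd.DataFrame({"i": [], "j": [], "r": [], "p": []}), 0.0)


class TestNetworkStrength:
    def test_empty_mask_gives_zero(self):
        assert nf.network_strength(np.eye(4), nf.EdgeMask()) == (0.0, 0.0)

    def test_single_edge_value_passed_through(self):
        m = np.eye(5)
        m[1, 3] = m[3, 1] = 0.37
        mask = nf.EdgeMask.from_edges(positive=[(1, 3)])
        assert nf.network_strength(m, mask) == (pytest.approx(0.37), 0.0)

    def test_matches_loop_sum_oracle(self):
        rng = np.random.default_rng(7)
        m = _random_matrices(rng, 1, 10)[0]
        pairs = [(i, j) for i in range(10) for j in range(i + 1, 10)]
        rng.shuffle(pairs)
        mask = nf.EdgeMask.from_edges(positive=pairs[:12], negative=pairs[12:20])
        pos, neg = nf.network_strength(m, mask)
        assert pos == pytest.approx(sum(m[i][j] for i, j in pairs[:12]), abs=1e-12)
        assert neg == pytest.approx(sum(m[i][j] for i, j in pairs[12:20]), abs=1e-12)


class TestEdgeMask:
    def test_overlap_rejected(self):
        with pytest.raises(ParameterError, match="overlap"):
            nf.EdgeMask(positive=frozenset({(0, 1)}), negative=frozenset({(0, 1)}))

    def test_self_pair_rejected(self):
        with pytest.raises(ParameterError, match="self-pair"):
            nf.EdgeMask(positive=frozenset({(2, 2)}))

    def test_file_round_trip(self, tmp_path):
        mask = nf.EdgeMask.from_edges(positive=[(3, 1), (0, 5)], negative=[(2, 4)])
        mask.write(tmp_path / "pos.edges", tmp_path / "neg.edges")
        back = nf.EdgeMask.read(tmp_path / "pos.edges", tmp_path / "neg.edges")
        assert back == mask


class TestFitPredict:
    def test_perfect_single_edge_signal_predicts_almost_exactly(self):
        rng = np.random.default_rng(8)
        mats = _random_matrices(rng, 50, 6)
        behavior = mats[:, 0, 1]
        res = nf.fit_predict(mats, behavior, scheme="loocv", p_threshold=0.01)
        assert res.r >= 0.99
        assert len(res.predicted) == 50

    def test_loocv_selection_ignores_held_out_subject(self, planted_cohort):
        """Leakage check: corrupting one subject's behavior must not change
        the mask of the fold holding that subject out."""
        _, _, cov, mats, truth = planted_cohort
        y = np.asarray(truth.latent_severity, dtype=float)
        res = nf.fit_predict(mats[:40], y[:40], cov.iloc[:40], scheme="loocv")
        y_corrupt = y[:40].copy()
        y_corrupt[7] = 40.0
        res_c = nf.fit_predict(mats[:40], y_corrupt, cov.iloc[:40], scheme="loocv")
        assert res.fold_masks[7] == res_c.fold_masks[7]
        # sanity: other folds (which train on subject 7) do differ
        assert any(res.fold_masks[i] != res_c.fold_masks[i] for i in range(40) if i != 7)

    def test_masks_disjoint_in_every_fold(self, planted_cohort):
        _, _, cov, mats, truth = planted_cohort
        res = nf.fit_predict(
            mats, truth.latent_severity, cov, scheme="kfold", k=5, repeats=3, seed=1
        )
        assert len(res.fold_masks) == 15
        for mask in res.fold_masks:
            assert not (mask.positive & mask.negative)

    def test_kfold_covers_every_subject_once_per_repeat(self, planted_cohort):
        _, _, cov, mats, truth = planted_cohort
        res = nf.fit_predict(
            mats, truth.latent_severity, cov, scheme="kfold", k=4, seed=2
        )
        assert np.isfinite(res.predicted).all()
        assert len(res.predicted) == len(res.observed)

    def test_planted_cohort_prediction_beats_null(self, planted_cohort, null_cohort):
        _, _, cov, mats, truth = planted_cohort
        res = nf.fit_predict(mats, truth.latent_severity, cov, scheme="loocv")
        ncfg, _, ncov, nmats, ntruth = null_cohort
        nres = nf.fit_predict(nmats, ntruth.latent_severity, ncov, scheme="loocv")
        assert res.r > 0.3 > nres.r

    def test_prediction_r_monotone_in_planted_effect(self):
        """Median cross-validated r never decreases over an effect-size grid."""
        frames, base = 120, 0.2
        medians = []
        for r_e in (0.0, 0.25, 0.5):
            eff = 0.0 if r_e == 0 else cal.effect_for_edge_severity_r(r_e, base, frames)
            rs = []
            for seed in range(5):
                cfg = nf.SimulationConfig(
                    n_subjects=80, n_nodes=10, frames_per_block=30,
                    n_blocks_per_condition=4, planted_pos_edges=((0, 1), (0, 2)),
                    planted_neg_edges=((3, 4), (5, 6)), effect_size=eff,
                    conditions=("punishment",), seed=40 + seed,
                )
                _, cov, series, truth = nf.simulate_cohort(cfg)
                mats = np.asarray(
                    [nf.connectivity_matrix(series["punishment"][i]).values
                     for i in range(80)]
                )
                rs.append(
                    nf.fit_predict(mats, truth.latent_severity, cov, scheme="loocv").r
                )
            medians.append(np.median(rs))
        assert medians[0] <= medians[1] <= medians[2]

    def test_degenerate_folds_fall_back_to_intercept(self):
        rng = np.random.default_rng(9)
        mats = _random_matrices(rng, 15, 4)
        behavior = rng.standard_normal(15)
        res = nf.fit_predict(mats, behavior, scheme="loocv", p_threshold=1e-9)
        assert res.degenerate_folds == 15
        # intercept-only folds predict the training mean; under LOOCV the
        # leave-one-out mean anti-correlates perfectly with the held-out value
        loo_means = (behavior.sum() - behavior) / 14
        assert np.allclose(res.predicted, loo_means, atol=1e-12)

    def test_invalid_arguments_rejected(self):
        mats = _random_matrices(np.random.default_rng(10), 12, 4)
        y = np.arange(12.0)
        with pytest.raises(ParameterError, match="scheme"):
            nf.fit_predict(mats, y, scheme="bootstrap")
        with pytest.raises(ParameterError, match="k must"):
            nf.fit_predict(mats, y, scheme="kfold", k=1)
        with pytest.raises(ParameterError, match="network"):
            nf.fit_predict(mats, y, network="both")


class TestPermutationTest:
    def test_p_floor_when_observed_beats_all_permutations(self):
        rng = np.random.default_rng(11)
        mats = _random_matrices(rng, 40, 5)
        behavior = mats[:, 0, 1]  # perfect signal: r_obs ~ 1
        perm = nf.permutation_test(
            mats, behavior, n_perm=19, seed=0, scheme="loocv"
        )
        assert perm.p == pytest.approx(1.0 / 20.0)
        assert perm.r_observed >= 0.99

    def test_same_seed_reproduces_p(self, null_cohort):
        _, _, cov, mats, truth = null_cohort
        a = nf.permutation_test(
            mats, truth.latent_severity, cov, n_perm=25, seed=7, scheme="kfold", k=4
        )
        b = nf.permutation_test(
            mats, truth.latent_severity, cov, n_perm=25, seed=7, scheme="kfold", k=4
        )
        assert a.p == b.p
        assert np.array_equal(a.r_permuted, b.r_permuted)

    def test_result_object_updated(self, null_cohort):
        _, _, cov, mats, truth = null_cohort
        res = nf.fit_predict(
            mats, truth.latent_severity, cov, scheme="kfold", k=4, seed=3
        )
        perm = nf.permutation_test(
            mats, truth.latent_severity, cov, n_perm=9, seed=3, result=res
        )
        assert res.p == perm.p
        assert res.n_permutations == 9
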