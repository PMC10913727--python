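import itertools

import numpy as np
import pytest

from mssid.evaluate import (
    align_models,
    blocked_cv_splits,
    cost_term_norms,
    fit_behavior_decoder,
    normalized_error,
    normalized_mode_error,
    predict_behavior,
    prediction_cc,
    prediction_power,
    select_state_dim,
)
from mssid.params import CovParams, pset_from_nset
from tests.conftest import random_stable_params


def transformed_copy(ps, T_mat):
    Ti = np.linalg.inv(T_mat)
    return CovParams(
        A=Ti @ ps.A @ T_mat, C_z=ps.C_z @ T_mat, C_y=ps.C_y @ T_mat,
        G_z=Ti @ ps.G_z, G_y=Ti @ ps.G_y, Lambda0=ps.Lambda0.copy(),
        d_z=ps.d_z.copy(), Sigma_x=Ti @ ps.Sigma_x @ Ti.T,
    )


class TestAlignment:
    def test_exact_similarity_recovery(self):
        ps = pset_from_nset(random_stable_params(4))
        rng = np.random.default_rng(0)
        T_mat = rng.standard_normal((3, 3)) + np.eye(3)
        learned = transformed_copy(ps, T_mat)
        aligned = align_models(learned, ps)
        for a, b in ((aligned.A, ps.A), (aligned.C_z, ps.C_z), (aligned.C_y, ps.C_y),
                     (aligned.G_z, ps.G_z), (aligned.G_y, ps.G_y)):
            assert normalized_error(a, b) < 1e-8

    def test_identity_when_already_aligned(self):
        ps = pset_from_nset(random_stable_params(6))
        aligned = align_models(ps, ps)
        assert normalized_error(aligned.A, ps.A) < 1e-10

    def test_eigenvalues_invariant_under_alignment(self):
        ps = pset_from_nset(random_stable_params(8))
        rng = np.random.default_rng(1)
        learned = transformed_copy(ps, rng.standard_normal((3, 3)) + 2 * np.eye(3))
        aligned = align_models(learned, ps)
        assert np.allclose(np.sort_complex(np.linalg.eigvals(aligned.A)),
                           np.sort_complex(np.linalg.eigvals(learned.A)), atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        a = pset_from_nset(random_stable_params(1, n_z=2))
        b = pset_from_nset(random_stable_params(1, n_z=3))
        with pytest.raises(ValueError):
            align_models(a, b)


class TestNormalizedError:
    @pytest.mark.parametrize("factor,expected", [(1.0, 0.0), (0.0, 1.0), (2.0, 1.0)])
    def test_scaling_identities(self, factor, expected):
        psi = np.arange(1.0, 7.0).reshape(2, 3)
        assert np.isclose(normalized_error(factor * psi, psi), expected)

    def test_zero_truth_rejected(self):
        with pytest.raises(ValueError):
            normalized_error(np.ones(3), np.zeros(3))


class TestModeError:
    def test_identical_spectra(self):
        A = random_stable_params(2).A
        assert normalized_mode_error(A, A) == 0.0

    def test_permutation_invariance(self):
        A = np.diag([0.9, 0.5, 0.3])
        B = np.diag([0.3, 0.9, 0.5])
        assert normalized_mode_error(B, A) < 1e-14

    def test_matches_exhaustive_permutation_oracle(self):
        rng = np.random.default_rng(3)
        ev_true = rng.uniform(0.2, 0.99, 3)
        ev_id = ev_true + rng.normal(0, 0.05, 3)
        got = normalized_mode_error(np.diag(ev_id), np.diag(ev_true))
        best = min(
            np.linalg.norm(ev_true - np.array(perm))
            for perm in itertools.permutations(ev_id)
        ) / np.linalg.norm(ev_true)
        assert np.isclose(got, best)

    def test_subset_restriction(self):
        A_true = np.diag([0.9, 0.5])
        A_id = np.diag([0.9, 0.1])
        full = normalized_mode_error(A_id, A_true)
        only_good = normalized_mode_error(A_id, A_true, mode_subset=np.array([0.9]))
        assert only_good < 1e-12 < full

    def test_subset_too_large_rejected(self):
        with pytest.raises(ValueError):
            normalized_mode_error(np.diag([0.5]), np.diag([0.5]),
                                  mode_subset=np.array([0.5, 0.4]))


class TestCostTermNorms:
    def test_exact_model_has_zero_cost_terms(self, small_model):
        ps = pset_from_nset(small_model)
        n_z = ps.n_z
        norms = cost_term_norms(
            R_z=np.zeros((n_z, n_z)), R_zy=np.zeros((n_z, ps.n_y)),
            S=np.zeros((ps.n_x, n_z + ps.n_y)), R_y=small_model.R_y,
            Lambda0=ps.Lambda0, G=np.hstack([ps.G_z, ps.G_y]), n_z=n_z,
        )
        assert norms["R_z"] == 0.0 and norms["R_zy"] == 0.0 and norms["S"] == 0.0
        assert norms["R_y"] > 0.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            cost_term_norms(np.zeros((1, 1)), np.zeros((1, 1)), np.zeros((1, 2)),
                            np.zeros((1, 1)), np.zeros((2, 2)), np.ones((1, 2)), 1)


class TestPredictionPower:
    def test_perfect_ranking(self):
        events = np.array([[1], [0], [1], [0]])
        p = np.array([[0.9], [0.1], [0.8], [0.2]])
        assert prediction_power(events, p) == 1.0

    def test_constant_probability_is_chance(self):
        events = np.array([[1], [0], [1], [0]])
        p = np.full((4, 1), 0.5)
        assert prediction_power(events, p) == 0.0

    def test_six_bin_toy_matches_pairwise_counting(self):
        events = np.array([1, 0, 1, 0, 0, 0])[:, None]
        p = np.array([0.9, 0.2, 0.6, 0.7, 0.1, 0.3])[:, None]
        # brute-force AUC: fraction of (event, non-event) pairs ranked correctly
        pos = p[events[:, 0] == 1, 0]
        neg = p[events[:, 0] == 0, 0]
        auc = np.mean([(a > b) + 0.5 * (a == b) for a in pos for b in neg])
        assert np.isclose(auc, 7 / 8)
        assert np.isclose(prediction_power(events, p), 2 * auc - 1)

    def test_all_single_class_rejected(self):
        with pytest.raises(ValueError):
            prediction_power(np.zeros((5, 2)), np.random.rand(5, 2))


class TestPredictionCC:
    def test_identity_and_sign(self):
        y = np.random.default_rng(0).standard_normal((50, 2))
        assert np.isclose(prediction_cc(y, y), 1.0)
        assert np.isclose(prediction_cc(y, -y), -1.0)

    def test_affine_invariance(self):
        y = np.random.default_rng(1).standard_normal((50, 2))
        assert np.isclose(prediction_cc(y, 3.0 * y + 2.0), 1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            prediction_cc(np.ones((10, 1)), np.random.rand(10, 1))


class TestBehaviorDecoder:
    def test_noiseless_linear_behavior(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((200, 4))
        L_true = rng.standard_normal((3, 5))
        b = predict_behavior(L_true, x)
        L = fit_behavior_decoder(x, b)
        assert np.allclose(L, L_true, atol=1e-9)
        assert np.isclose(prediction_cc(b, predict_behavior(L, x)), 1.0)

    def test_constant_states_reduce_to_mean(self):
        x = np.zeros((100, 2))
        b = np.full((100, 1), 4.2) + np.random.default_rng(3).normal(0, 0.1, (100, 1))
        with pytest.warns(RuntimeWarning):
            L = fit_behavior_decoder(x, b)
        assert np.isclose(L[0, 0], b.mean(), atol=1e-6)

    def test_matches_qr_solver_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((60, 3))
        b = rng.standard_normal((60, 2))
        L = fit_behavior_decoder(x, b)
        X = np.hstack([np.ones((60, 1)), x])
        Qm, Rm = np.linalg.qr(X)
        L_qr = np.linalg.solve(Rm, Qm.T @ b).T
        assert np.allclose(L, L_qr, atol=1e-10)


class TestCrossValidation:
    def test_five_equal_blocks(self):
        splits = blocked_cv_splits(10, 5)
        tests = [s[1].tolist() for s in splits]
        assert tests == [[0, 1], [2, 3], [4, 5], [6, 7], [8, 9]]

    def test_exhaustive_and_disjoint(self):
        splits = blocked_cv_splits(103, 5)
        all_test = np.concatenate([s[1] for s in splits])
        assert sorted(all_test.tolist()) == list(range(103))
        assert len(set(all_test.tolist())) == 103
        for train, test in splits:
            assert set(train) & set(test) == set()

    def test_single_fold_rejected(self):
        with pytest.raises(ValueError):
            blocked_cv_splits(10, 1)


class TestStateDimSelection:
    def test_single_candidate_passthrough(self):
        assert select_state_dim(lambda n, tr, te: 0.5, T=100, candidates=[6]) == 6

    def test_deterministic_and_prefers_best_score(self):
        scores = {2: 0.1, 4: 0.9, 8: 0.7}
        pick = select_state_dim(lambda n, tr, te: scores[n], T=100, candidates=[2, 4, 8])
        assert pick == 4
        assert pick == select_state_dim(lambda n, tr, te: scores[n], T=100,
                                        candidates=[8, 2, 4])

    def test_under_modeling_penalized_on_simulated_data(self, study_model):
        """Data from an 8-state model should never select 2 states."""
        from mssid.estimator import MultiscaleSID
        from mssid.evaluate import prediction_cc as cc
        from mssid.simulate import MultimodalData, simulate_data

        _, model, _ = study_model
        rng = np.random.default_rng(0)
        L_beh = rng.standard_normal((2, model.n_x))
        picks = []
        for seed in range(3):
            d = simulate_data(model, T=12_000, M=5, seed=100 + seed)
            behavior = d.x @ L_beh.T + 0.1 * rng.standard_normal((d.T, 2))

            def fit_score(n_x, tr, te):
                train = MultimodalData(N=d.N[tr], y=d.y[tr], mask=d.mask[tr], M=5)
                test = MultimodalData(N=d.N[te], y=d.y[te], mask=d.mask[te], M=5)
                est = MultiscaleSID(n_x=n_x, h_z=6, h_y=6).fit(train)
                xf = est.filter(test).x_filt
                L = fit_behavior_decoder(est.filter(train).x_filt, behavior[tr])
                return cc(behavior[te], predict_behavior(L, xf))

            picks.append(select_state_dim(fit_score, T=d.T, candidates=[2, 4, 8]))
        assert all(p != 2 for p in picks)

    def test_all_failures_raise(self):
        def boom(n, tr, te):
            raise RuntimeError("nope")
        with pytest.raises(RuntimeError, match="failed"):
            select_state_dim(boom, T=10, candidates=[1, 2])
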