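import numpy as np
import pytest

from mdfldrr import Hyperparameters, fit, learn_relation_structure
from mdfldrr.projection import (
    full_objective,
    predict_new_drug,
    predict_within,
    reduced_objective,
    solve_S,
    update_Z,
)

from conftest import random_instance


def brute_force_full_objective(Hs, Zs, S, J, M, hp):
    """Loop-based elementwise evaluation of the joint objective."""
    n = J.shape[0]
    theta, lam, sigma = hp.theta, hp.lambda_sparsity, hp.sigma
    total = 0.0
    for H, Z in zip(Hs, Zs):
        HZ = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                HZ[i, j] = sum(H[i, k] * Z[k, j] for k in range(H.shape[1]))
        total += theta * sum(
            (S[i, j] - HZ[i, j]) ** 2 + (J[i, j] - HZ[i, j]) ** 2
            for i in range(n)
            for j in range(n)
        )
        for X in (Z, H):
            total += lam * sum(X[:, j].sum() ** 2 for j in range(X.shape[1]))
    total += sum((S[i, j] - J[i, j]) ** 2 for i in range(n) for j in range(n))
    if sigma:
        for i in range(n):
            for j in range(n):
                resid = S[i, j] - sum(M[i, l] * S[l, j] for l in range(n))
                total += sigma * resid**2
    return total


def random_Zs(Hs, n, seed):
    rng = np.random.default_rng(seed)
    return [rng.uniform(0, 1, (H.values.shape[1], n)) for H in Hs]


def fitted_M(J, seed=0):
    return learn_relation_structure(J, theta_drr=1e-2, seed=seed)


class TestFullObjective:
    def test_all_zero_inputs_give_zero(self):
        hp = Hyperparameters(sigma=0.0)
        Hs = [np.zeros((3, 2))]
        assert full_objective(Hs, [np.zeros((2, 3))], np.zeros((3, 3)),
                              np.zeros((3, 3)), None, hp) == 0.0

    def test_plug_in_value_at_S_equals_J(self):
        rng = np.random.default_rng(0)
        H = (rng.random((4, 3)) < 0.5).astype(float)
        J = np.zeros((4, 4)); J[0, 1] = J[1, 0] = 1.0
        hp = Hyperparameters(theta=0.2, lambda_sparsity=0.3, sigma=0.0)
        Z = np.zeros((3, 4))
        expected = (
            hp.theta * 2 * np.linalg.norm(J) ** 2
            + hp.lambda_sparsity * np.sum(H.sum(axis=0) ** 2)
        )
        assert full_objective([H], [Z], J.copy(), J, None, hp) == pytest.approx(expected)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_loop_oracle(self, seed):
        Hs, J = random_instance(seed, n=6, m=2, dims=(4, 5))
        hp = Hyperparameters(lambda_sparsity=0.05, theta=0.1, sigma=0.02)
        M = fitted_M(J, seed)
        Zs = random_Zs(Hs, 6, seed)
        S = np.random.default_rng(seed + 1).normal(size=(6, 6))
        ours = full_objective(Hs, Zs, S, J, M, hp)
        oracle = brute_force_full_objective(
            [H.values for H in Hs], Zs, S, J.values, M.M, hp
        )
        assert ours == pytest.approx(oracle, rel=1e-9)


class TestSolveS:
    def test_identity_limit_returns_J(self):
        # theta -> tiny, sigma = 0: S ~= J (exactly J at theta = 0 limit)
        Hs, J = random_instance(0, n=5, m=1, dims=(4,))
        hp = Hyperparameters(theta=0.0, sigma=0.0, lambda_sparsity=0.1)
        S = solve_S(Hs, [np.zeros((4, 5))], J, None, hp)
        np.testing.assert_allclose(S, J.values, atol=1e-12)

    def test_consistent_projection_fixed_point(self):
        # sigma=0, m=1, H Z = J  =>  S = ((1+theta)I)^-1 (theta J + J) = J
        n = 4
        H = np.eye(n)
        J = np.zeros((n, n)); J[0, 1] = J[1, 0] = 1.0
        hp = Hyperparameters(theta=0.3, sigma=0.0)
        S = solve_S([H], [J.copy()], J, None, hp)
        np.testing.assert_allclose(S, J, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_central_difference_gradient_vanishes(self, seed):
        Hs, J = random_instance(seed, n=8, m=2, dims=(6, 7))
        hp = Hyperparameters(lambda_sparsity=1e-1, theta=1e-2, sigma=1e-2)
        M = fitted_M(J, seed)
        Zs = random_Zs(Hs, 8, seed)
        S = solve_S(Hs, Zs, J, M, hp)
        eps = 1e-6
        gmax = 0.0
        for i in range(8):
            for j in range(8):
                E = np.zeros_like(S); E[i, j] = eps
                g = (
                    full_objective(Hs, Zs, S + E, J, M, hp)
                    - full_objective(Hs, Zs, S - E, J, M, hp)
                ) / (2 * eps)
                gmax = max(gmax, abs(g))
        assert gmax <= 1e-5

    def test_residual_is_tiny(self):
        Hs, J = random_instance(3, n=7, m=2, dims=(5, 6))
        hp = Hyperparameters(theta=0.05, sigma=0.01)
        M = fitted_M(J)
        Zs = random_Zs(Hs, 7, 3)
        S = solve_S(Hs, Zs, J, M, hp)
        from mdfldrr.projection import _system_matrix
        A = _system_matrix(M.M, 2, hp)
        rhs = J.values + hp.theta * sum(H.values @ Z for H, Z in zip(Hs, Zs))
        resid = np.linalg.norm(A @ S - rhs) / np.linalg.norm(rhs)
        assert resid <= 1e-8


class TestReducedObjective:
    @pytest.mark.parametrize("seed", range(3))
    def test_differences_match_full_objective_differences(self, seed):
        Hs, J = random_instance(seed, n=6, m=2, dims=(4, 5))
        hp = Hyperparameters(lambda_sparsity=0.05, theta=0.1, sigma=0.01)
        M = fitted_M(J, seed)
        Za = random_Zs(Hs, 6, seed + 100)
        Zb = random_Zs(Hs, 6, seed + 200)
        d_red = reduced_objective(Hs, Za, J, M, hp) - reduced_objective(Hs, Zb, J, M, hp)
        fa = full_objective(Hs, Za, solve_S(Hs, Za, J, M, hp), J, M, hp)
        fb = full_objective(Hs, Zb, solve_S(Hs, Zb, J, M, hp), J, M, hp)
        assert d_red == pytest.approx(fa - fb, rel=1e-7, abs=1e-7)

    def test_offset_is_the_feature_norm_constant(self):
        Hs, J = random_instance(1, n=5, m=1, dims=(4,))
        hp = Hyperparameters(lambda_sparsity=0.2, theta=0.1, sigma=0.0)
        Zs = [np.zeros((4, 5))]
        S = solve_S(Hs, Zs, J, None, hp)
        const = hp.lambda_sparsity * np.sum(Hs[0].values.sum(axis=0) ** 2)
        assert reduced_objective(Hs, Zs, J, None, hp) == pytest.approx(
            full_objective(Hs, Zs, S, J, None, hp) - const
        )


class TestUpdateZ:
    def test_zero_projection_stays_zero(self):
        Hs, J = random_instance(0, n=5, m=2, dims=(4, 4))
        hp = Hyperparameters(theta=0.1, sigma=0.0)
        Zs = [np.zeros((4, 5)), np.zeros((4, 5))]
        out = update_Z(Hs, Zs, J, None, hp)
        assert all(np.all(Z == 0) for Z in out)

    @pytest.mark.parametrize("seed", range(5))
    def test_nonnegativity_closure_and_monotone_trace(self, seed):
        Hs, J = random_instance(seed, n=6, m=2, dims=(5, 4))
        hp = Hyperparameters(lambda_sparsity=1e-2, theta=1e-2, sigma=1e-3)
        M = fitted_M(J, seed)
        Zs = random_Zs(Hs, 6, seed)
        prev = full_objective(Hs, Zs, solve_S(Hs, Zs, J, M, hp), J, M, hp)
        for _ in range(5):
            Zs = update_Z(Hs, Zs, J, M, hp)
            assert all((Z >= 0).all() for Z in Zs)
            cur = full_objective(Hs, Zs, solve_S(Hs, Zs, J, M, hp), J, M, hp)
            assert cur <= prev + 1e-8 * max(abs(prev), 1.0)
            prev = cur


class TestFit:
    def test_deterministic_under_seed(self, small_ds):
        hp = Hyperparameters.goal1(seed=3, max_iter=10)
        a = fit(small_ds.Hs, small_ds.J, hp)
        b = fit(small_ds.Hs, small_ds.J, hp)
        np.testing.assert_array_equal(a.S, b.S)
        for Za, Zb in zip(a.Zs, b.Zs):
            np.testing.assert_array_equal(Za, Zb)

    def test_objective_history_non_increasing(self, small_ds):
        hp = Hyperparameters.goal1(seed=0, max_iter=20)
        model = fit(small_ds.Hs, small_ds.J, hp)
        h = np.asarray(model.objective_history)
        assert np.all(np.diff(h) <= 1e-8 * np.maximum(np.abs(h[:-1]), 1.0))
        assert model.converged_at <= hp.max_iter

    def test_sigma_zero_ignores_relation_structure(self, small_ds):
        hp = Hyperparameters.goal2(seed=1, max_iter=10)
        model = fit(small_ds.Hs, small_ds.J, hp)
        assert np.all(model.relation.M == 0)

    def test_sigma_limit_matches_sigma_zero(self, small_ds):
        hp0 = Hyperparameters.goal1(sigma=0.0, seed=2, max_iter=15)
        hp_eps = Hyperparameters.goal1(sigma=1e-12, seed=2, max_iter=15)
        f0 = fit(small_ds.Hs, small_ds.J, hp0).objective_history[-1]
        fe = fit(small_ds.Hs, small_ds.J, hp_eps).objective_history[-1]
        assert abs(f0 - fe) / abs(f0) < 1e-6


@pytest.fixture(scope="module")
def goal1_model(small_ds):
    return fit(small_ds.Hs, small_ds.J, Hyperparameters.goal1(seed=0))


@pytest.fixture(scope="module")
def goal2_model(small_ds):
    return fit(small_ds.Hs, small_ds.J, Hyperparameters.goal2(seed=0))


class TestPredictWithin:
    def test_scores_are_symmetrized(self, goal1_model, small_ds):
        a, b = small_ds.catalog.ids[0], small_ds.catalog.ids[1]
        (row,) = predict_within(goal1_model, [(a, b)])
        i, j = 0, 1
        assert row[2] == pytest.approx(0.5 * (goal1_model.S[i, j] + goal1_model.S[j, i]))

    def test_self_pair_rejected(self, goal1_model, small_ds):
        a = small_ds.catalog.ids[0]
        with pytest.raises(ValueError):
            predict_within(goal1_model, [(a, a)])

    def test_known_pairs_flagged(self, goal1_model, small_ds):
        a, b = small_ds.J.pairs()[0]
        (row,) = predict_within(goal1_model, [(a, b)])
        assert row[3] is True

    def test_unknown_drug_errors(self, goal1_model):
        with pytest.raises(KeyError):
            predict_within(goal1_model, [("nope", "alsono")])

    def test_latent_neighbours_outrank_strangers(self, goal1_model, small_ds):
        # pairs close in the planted latent space should score above far pairs
        U = small_ds.latent
        A = U @ U.T
        n = len(small_ds.catalog)
        iu, ju = np.triu_indices(n, k=1)
        unseen = small_ds.J.values[iu, ju] == 0
        affinity = A[iu, ju][unseen]
        Ssym = 0.5 * (goal1_model.S + goal1_model.S.T)
        scores = Ssym[iu, ju][unseen]
        top = affinity >= np.quantile(affinity, 0.9)
        assert scores[top].mean() > scores[~top].mean()


class TestPredictNewDrug:
    def test_all_zero_features_give_zero_scores(self, goal2_model, small_ds):
        feats = {H.feature_name: np.zeros(H.n_descriptors) for H in small_ds.Hs}
        np.testing.assert_array_equal(predict_new_drug(goal2_model, feats), 0.0)

    def test_single_view_plug_in(self, small_ds):
        # m = 1: feature row k of H gives (H Z)_k / 2
        model = fit(small_ds.Hs[:1], small_ds.J, Hyperparameters.goal2(seed=0))
        H = small_ds.Hs[0]
        k = 3
        expected = (H.values @ model.Zs[0])[k] / 2.0
        got = predict_new_drug(model, {H.feature_name: H.values[k]})
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_dimension_mismatch_names_feature_space(self, goal2_model):
        with pytest.raises(ValueError, match="pathway"):
            predict_new_drug(goal2_model, {"pathway": np.zeros(3)})

    def test_missing_feature_space_contributes_zero(self, goal2_model, small_ds):
        feats = {small_ds.Hs[0].feature_name: small_ds.Hs[0].values[0]}
        partial = predict_new_drug(goal2_model, feats)
        assert (partial >= 0).all()

    def test_held_out_drug_ranks_true_interactors_higher(self, small_ds):
        from mdfldrr import generate_holdout_drugs

        train, holds = generate_holdout_drugs(small_ds, 0.2)
        model = fit(train.Hs, train.J, Hyperparameters.goal2(seed=0))
        informative = [h for h in holds if 0 < h["labels"].sum() < len(h["labels"])]
        assert informative
        wins = sum(
            predict_new_drug(model, h["features"])[h["labels"] == 1].mean()
            > predict_new_drug(model, h["features"])[h["labels"] == 0].mean()
            for h in informative
        )
        assert wins / len(informative) >= 0.8
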