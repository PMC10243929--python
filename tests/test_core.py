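import numpy as np
import pytest

from honmf import (
    HONMF,
    HONMFConfig,
    HONMFState,
    auto_select_params,
    initialize,
    objective,
    simulate_multiomics,
    update_step,
)
from honmf.core import iterate, nndsvd_symmetric

from conftest import fit_synthetic


def _cfg(**kw):
    base = dict(k=2, alpha=1.0, beta=1.0, gamma=1.0, eta=10.0)
    base.update(kw)
    return HONMFConfig(**base)


def _zero_state(n, k, M):
    return HONMFState([np.zeros((n, k)) for _ in range(M)],
                      [np.zeros((k, k)) for _ in range(M)], np.zeros((n, n)))


def _exact_fit_instance():
    """A global optimum: block-indicator H with orthonormal columns."""
    n, k = 6, 3
    H = np.zeros((n, k))
    for c in range(k):
        H[2 * c: 2 * c + 2, c] = 1.0 / np.sqrt(2.0)
    G = np.eye(k)
    A = H @ G @ H.T
    S = H @ H.T  # rows sum to 1 exactly
    # hyperedges = the blocks: H is block-constant, so the regularizer is 0
    from honmf import Hypergraph, hypergraph_laplacian

    P = np.zeros((n, k))
    for c in range(k):
        P[2 * c: 2 * c + 2, c] = 1.0
    L = hypergraph_laplacian(Hypergraph(P, np.ones(k)))
    return H, G, A, S, L


class TestObjective:
    def test_all_zero_state_term_by_term(self):
        # eta*M*k + beta*n with everything else zero
        n, k, M = 5, 2, 3
        cfg = _cfg(k=k, alpha=3.0, gamma=7.0)
        state = _zero_state(n, k, M)
        A_list = [np.zeros((n, n))] * M
        L_list = [np.zeros((n, n))] * M
        assert objective(state, A_list, L_list, cfg) == pytest.approx(10 * 3 * 2 + 5)

    def test_exact_factorization_leaves_only_regularizer(self):
        H, G, A, S, L = _exact_fit_instance()
        cfg = _cfg(k=3, alpha=2.0, gamma=5.0)
        state = HONMFState([H], [G], S)
        val = objective(state, [A], [L], cfg)
        assert val == pytest.approx(0.0, abs=1e-12)

    def test_nonnegative_for_random_states(self, rng):
        n, k = 7, 2
        cfg = _cfg(alpha=0.5, gamma=0.3)
        for _ in range(10):
            state = HONMFState([rng.uniform(0, 1, (n, k))], [rng.uniform(0, 1, (k, k))],
                               rng.uniform(0, 1, (n, n)))
            A = rng.uniform(0, 1, (n, n))
            L_raw = np.diag(rng.uniform(1, 2, n))  # PSD stand-in Laplacian term
            assert objective(state, [A], [L_raw], cfg) >= 0.0

    def test_auto_alpha_rejected(self):
        cfg = HONMFConfig(k=2)  # alpha/gamma still "auto"
        with pytest.raises(ValueError, match="numeric"):
            objective(_zero_state(4, 2, 1), [np.zeros((4, 4))], None, cfg)


class TestInitialize:
    def test_deterministic(self, rng):
        A = rng.uniform(0, 1, (8, 8))
        A = 0.5 * (A + A.T)
        cfg = _cfg(k=3)
        s1 = initialize([A], cfg)
        s2 = initialize([A], cfg)
        np.testing.assert_array_equal(s1.H[0], s2.H[0])
        np.testing.assert_array_equal(s1.S, s2.S)

    def test_mixing_matrices_start_at_identity(self, rng):
        A = rng.uniform(0, 1, (6, 6))
        A = 0.5 * (A + A.T)
        st = initialize([A, A], _cfg(k=2))
        for G in st.G:
            np.testing.assert_array_equal(G, np.eye(2))

    def test_nndsvd_residual_bounded_by_matrix_norm(self):
        # A = B B^T with non-negative orthogonal columns is exactly rank-k
        B = np.zeros((6, 2))
        B[:3, 0] = [1.0, 2.0, 1.0]
        B[3:, 1] = [2.0, 1.0, 2.0]
        A = B @ B.T
        H = nndsvd_symmetric(A, 2)
        resid = np.linalg.norm(A - H @ H.T)
        # truncated eigendecomposition oracle: best rank-2 residual is 0,
        # the non-negative init must at least beat the trivial H=0 fit
        assert resid <= np.linalg.norm(A)
        assert (H >= 0).all()

    def test_k_larger_than_n_rejected(self, rng):
        A = np.eye(4)
        with pytest.raises(ValueError, match="exceeds"):
            initialize([A], _cfg(k=5))


class TestAutoSelectParams:
    def test_ratios_match_independent_recomputation(self, rng):
        n, k = 7, 2
        A = rng.uniform(0, 1, (n, n))
        A = 0.5 * (A + A.T)
        Lv = np.diag(np.full(n, 2.0)) - 2.0 / n * np.ones((n, n))
        Lv -= np.diag(Lv.sum(axis=1))  # zero row sums
        cfg = _cfg(k=k)
        st = initialize([A], cfg)
        alpha, gamma = auto_select_params([A], [Lv], st)
        H, G = st.H[0], st.G[0]
        num = ((A - H @ G @ H.T) ** 2).sum()
        assert alpha == pytest.approx(num / ((st.S - H @ H.T) ** 2).sum(), rel=1e-12)
        assert gamma == pytest.approx(num / np.trace(H.T @ Lv @ H), rel=1e-12)

    def test_zero_denominator_falls_back_with_warning(self):
        H, G, A, S, L = _exact_fit_instance()
        st = HONMFState([H], [G], S)
        with pytest.warns(UserWarning, match="alpha"):
            alpha, gamma = auto_select_params([A], [L.values], st)
        assert alpha == 1.0 and gamma == 1.0


class TestUpdateStep:
    def test_exact_fit_is_fixed_point(self):
        H, G, A, S, L = _exact_fit_instance()
        cfg = _cfg(k=3, alpha=2.0, gamma=5.0)
        st = HONMFState([H], [G], S)
        new = update_step(st, [A], [L], cfg)
        assert np.abs(new.H[0] - H).max() < 1e-8
        assert np.abs(new.G[0] - G).max() < 1e-8
        assert np.abs(new.S - S).max() < 1e-8

    def test_objective_monotone_from_random_init(self, rng):
        ds, _ = simulate_multiomics(12, 2, [14, 10], 0.6, seed=11)
        model = HONMF(ds, k=2, seed=11)
        A_list = [A.values for A in model.affinities()]
        L_list = model.laplacians()
        cfg = model.config.resolved(0.8, 0.4)
        n = 12
        st = HONMFState([rng.uniform(0, 1, (n, 2)) for _ in range(2)],
                        [np.eye(2) for _ in range(2)], rng.uniform(0, 1, (n, n)))
        prev = objective(st, A_list, L_list, cfg)
        for _ in range(200):
            st = update_step(st, A_list, L_list, cfg)
            cur = objective(st, A_list, L_list, cfg)
            assert cur <= prev * (1 + 1e-8) + 1e-12
            prev = cur

    def test_factors_stay_nonnegative(self, rng):
        ds, _ = simulate_multiomics(12, 2, [14, 10], 0.6, seed=4)
        model = HONMF(ds, k=2, seed=4)
        A_list = [A.values for A in model.affinities()]
        L_list = model.laplacians()
        cfg = model.config.resolved(1.0, 1.0)
        st = initialize(A_list, cfg)
        for _ in range(100):
            st = update_step(st, A_list, L_list, cfg)
        assert all((H >= 0).all() for H in st.H)
        assert all((G >= 0).all() for G in st.G)
        assert (st.S >= 0).all()
        for G in st.G:
            np.testing.assert_allclose(G, G.T, atol=1e-8)


class TestFit:
    def test_variant_no_eta_drops_orthogonality_term(self, small_dataset):
        ds, _ = small_dataset
        res = HONMF(ds, k=3, seed=0, variant="no_eta", max_iter=30).fit()
        assert res.config.eta == 0.0

    def test_two_modality_path_runs(self):
        ds, truth = simulate_multiomics(30, 3, [40, 30], 1.0, seed=2)
        res = HONMF(ds, k=3, seed=2).fit()
        assert res.S.n_samples == 30
        assert len(res.H) == 2

    def test_orthogonality_pressure_reduces_gap(self, fitted_grid):
        ds, truth, res = fitted_grid[0]
        model = HONMF(ds, k=3, seed=0)
        A_list = [A.values for A in model.affinities()]
        init = initialize(A_list, model.config)
        k = 3
        init_gaps = [np.linalg.norm(H.T @ H - np.eye(k)) for H in init.H]
        assert all(g_fit < g0 for g_fit, g0 in zip(res.orthogonality_gaps(), init_gaps))

    def test_consensus_gap_shrinks_from_init(self, fitted_grid):
        ds, truth, res = fitted_grid[1]
        model = HONMF(ds, k=3, seed=1)
        A_sim = model.affinities()
        from honmf import snf_fuse

        S0 = snf_fuse(A_sim).values
        init = initialize([A.values for A in A_sim], model.config, S_init=S0)
        init_gaps = [np.linalg.norm(S0 - H @ H.T) for H in init.H]
        assert all(g <= g0 for g, g0 in zip(res.consensus_gaps(), init_gaps))

    def test_permutation_equivariance_of_consensus(self):
        ds, truth = simulate_multiomics(20, 2, [20, 16], 1.0, seed=6)
        rng = np.random.default_rng(0)
        perm = rng.permutation(20)
        from honmf import AbundanceMatrix, MultiOmicsDataset

        perm_mods = [
            AbundanceMatrix(m.values[:, perm], m.feature_ids,
                            [m.sample_ids[j] for j in perm], m.name)
            for m in ds.modalities
        ]
        ds_p = MultiOmicsDataset(perm_mods, ds.modality_names)
        res = HONMF(ds, k=2, seed=6, max_iter=150).fit()
        res_p = HONMF(ds_p, k=2, seed=6, max_iter=150).fit()
        np.testing.assert_allclose(
            res_p.state.S, res.state.S[np.ix_(perm, perm)], atol=1e-6
        )

    def test_objective_trace_recorded_and_monotone(self, fitted_grid):
        for seed in (0, 1, 2):
            _, _, res = fitted_grid[seed]
            tr = np.asarray(res.objective_trace)
            assert len(tr) == res.n_iter + 1
            assert (np.diff(tr) <= 1e-8 * np.abs(tr[:-1]) + 1e-12).all()

    def test_from_dataframes_constructor(self, small_dataset):
        ds, _ = small_dataset
        frames = [m.to_frame() for m in ds.modalities]
        model = HONMF.from_dataframes(frames, list(ds.modality_names), k=3, max_iter=5)
        res = model.fit()
        assert res.S.sample_ids == ds.sample_ids

    def test_summary_reports_key_quantities(self, fitted_grid):
        _, _, res = fitted_grid[0]
        text = res.summary()
        assert "alpha" in text and "gamma" in text
        assert "iterations" in text and str(res.config.k) in text

    def test_save_writes_all_artifacts(self, tmp_path, fitted_grid):
        _, _, res = fitted_grid[2]
        res.save(tmp_path / "out")
        names = {p.name for p in (tmp_path / "out").iterdir()}
        assert {"S.tsv", "objective_trace.tsv", "config.yaml",
                "H_bacteria.tsv", "G_virus.tsv"} <= names


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [dict(k=1), dict(eta=-1), dict(variant="foo"),
                                    dict(alpha=-0.5), dict(alpha="later")])
    def test_invalid_configs_rejected(self, kw):
        base = dict(k=3)
        base.update(kw)
        with pytest.raises(ValueError):
            HONMFConfig(**base)

    def test_variant_resolution_zeroes_terms(self):
        cfg = HONMFConfig(k=3, variant="no_alpha")
        r = cfg.resolved(5.0, 2.0)
        assert r.alpha == 0.0 and r.gamma == 2.0 and r.eta == 10.0
        cfg = HONMFConfig(k=3, variant="no_eta")
        assert cfg.resolved(1.0, 1.0).eta == 0.0
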