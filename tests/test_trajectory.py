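import numpy as np
import pytest

from bioclimdyn import polybasis as pb
from bioclimdyn import synthetic as sy
from bioclimdyn import trajectory as tj

_IDX = {e: k for k, e in enumerate(pb.EXPONENTS)}


def _linear_decay_model():
    C = np.zeros((3, 20))
    C[0, _IDX[(1, 0, 0)]] = -1.0
    C[1, _IDX[(0, 1, 0)]] = -1.0
    C[2, _IDX[(0, 0, 1)]] = -1.0
    return tj.PolyODEModel(coefficients=C)


class TestMonomialBasis:
    def test_origin(self):
        b = tj.monomial_basis(np.zeros(3))
        assert b[0] == 1.0 and np.all(b[1:] == 0)

    def test_ones(self):
        assert np.all(tj.monomial_basis(np.ones(3)) == 1.0)

    def test_x_powers(self):
        b = tj.monomial_basis(np.array([2.0, 0.0, 0.0]))
        assert list(np.nonzero(b)[0]) == [0, 1, 4, 10]
        np.testing.assert_allclose(b[[0, 1, 4, 10]], [1, 2, 4, 8])

    def test_basis_is_complete_cubic(self):
        assert len(pb.EXPONENTS) == 20
        assert all(sum(e) <= 3 for e in pb.EXPONENTS)
        assert len(set(pb.EXPONENTS)) == 20


class TestEvaluateRHS:
    def test_zero_model(self):
        m = tj.PolyODEModel(coefficients=np.zeros((3, 20)))
        np.testing.assert_array_equal(tj.evaluate_rhs(m, np.ones(3)), np.zeros(3))

    def test_linear_decay(self):
        m = _linear_decay_model()
        np.testing.assert_allclose(tj.evaluate_rhs(m, np.array([1.0, 2.0, 3.0])),
                                   [-1.0, -2.0, -3.0])

    def test_benchmark_fixed_point(self, benchmark):
        np.testing.assert_allclose(
            tj.evaluate_rhs(benchmark, np.array([125.0, 50.0, 8.8])),
            np.zeros(3), atol=1e-9)


class TestIntegrate:
    def test_zero_dynamics_constant(self):
        m = tj.PolyODEModel(coefficients=np.zeros((3, 20)))
        traj = tj.integrate(m, np.array([1.0, 2.0, 3.0]), 10, dt=1.0)
        assert not traj.diverged
        np.testing.assert_array_equal(traj.states, np.tile([1.0, 2.0, 3.0], (11, 1)))

    def test_exponential_decay_closed_form(self):
        m = _linear_decay_model()
        traj = tj.integrate(m, np.array([1.0, 0.0, 0.0]), 10, dt=1.0, substeps=4)
        assert traj.states[-1, 0] == pytest.approx(np.exp(-10.0), abs=1e-6)

    def test_benchmark_two_periods_returns_near_start(self, benchmark):
        x0 = sy.benchmark_cycle_state(0.3)
        traj = tj.integrate(benchmark, x0, horizon_months=1284, dt=1.0, substeps=4)
        diameter = 2 * np.sqrt(sy.BENCHMARK_LAMBDA) * sy.BENCHMARK_SCALE[0]
        assert np.linalg.norm(traj.states[-1] - x0) < 0.01 * diameter

    def test_blowup_flagged_not_raised(self):
        C = np.zeros((3, 20))
        C[0, _IDX[(1, 0, 0)]] = 5.0
        m = tj.PolyODEModel(coefficients=C)
        traj = tj.integrate(m, np.array([1.0, 0.0, 0.0]), 50, dt=1.0, guard=1e3)
        assert traj.diverged
        assert "month" in traj.message
        assert traj.states.shape[0] < 51


class TestQuality:
    def test_exact_generator_near_zero(self, benchmark, ident_monthly):
        rep = tj.quality(benchmark, ident_monthly, tj.TMConfig())
        assert rep.total <= 1e-6
        assert rep.stable

    def test_zero_dynamics_matches_direct_oracle(self, ident_monthly):
        m = tj.PolyODEModel(coefficients=np.zeros((3, 20)))
        cfg = tj.TMConfig()
        rep = tj.quality(m, ident_monthly, cfg)
        # oracle: constant trajectories, deviations straight from the data
        starts = np.arange(cfg.j_max) * cfg.d
        offsets = 2 ** np.arange(cfg.l_max)
        want = np.zeros(3)
        for j0 in starts:
            for off in offsets:
                want += np.abs(ident_monthly[j0 + off] - ident_monthly[j0])
        np.testing.assert_allclose(rep.q_components, want, rtol=1e-12)

    def test_perturbing_active_coefficient_increases_q(self, benchmark, ident_monthly):
        base = tj.quality(benchmark, ident_monthly).total
        C = benchmark.coefficients.copy()
        k = np.flatnonzero(np.abs(C[0]) > 0)[0]
        C[0, k] *= 1.10
        pert = tj.quality(tj.PolyODEModel(coefficients=C), ident_monthly).total
        assert pert > base

    def test_divergence_penalty(self, ident_monthly):
        C = np.zeros((3, 20))
        C[0, _IDX[(1, 0, 0)]] = 10.0
        rep = tj.quality(tj.PolyODEModel(coefficients=C), ident_monthly)
        cfg = tj.TMConfig()
        assert rep.total == pytest.approx(
            3 * cfg.divergence_penalty * cfg.j_max * cfg.l_max)
        assert not rep.stable

    def test_infeasible_config_rejected(self, ident_monthly):
        with pytest.raises(ValueError, match="infeasible"):
            tj.quality(tj.PolyODEModel(coefficients=np.zeros((3, 20))),
                       ident_monthly[:100], tj.TMConfig())


def _normal_form(model):
    return tj._to_scaled(model.coefficients, sy.BENCHMARK_OFFSET, sy.BENCHMARK_SCALE)


class TestInitCoefficients:
    def test_dense_recovery_within_one_percent(self, ident_dense):
        truth_nf = sy._benchmark_normal_form()
        active = np.abs(truth_nf) > 0
        model = tj.init_coefficients(ident_dense, ridge_weight=1e-12, dt=0.1)
        nf = _normal_form(model)
        rel = np.abs(nf[active] - truth_nf[active]) / np.abs(truth_nf[active])
        assert rel.max() < 0.01
        assert np.abs(nf[~active]).max() < 1e-4

    def test_constant_data_gives_near_zero_dynamics(self):
        data = np.tile([125.0, 50.0, 8.8], (100, 1))
        model = tj.init_coefficients(data, ridge_weight=1e-6)
        rhs = tj.evaluate_rhs(model, data[50])
        np.testing.assert_allclose(rhs, 0.0, atol=1e-9)
        # non-constant coefficients vanish (constant data carries no dynamics)
        assert np.abs(model.coefficients[:, 1:]).max() < 1e-9

    def test_monthly_recovery_trajectory_correlation(self, ident_monthly):
        model = tj.init_coefficients(ident_monthly, ridge_weight=1e-10, dt=1.0)
        traj = tj.integrate(model, ident_monthly[0], horizon_months=60, dt=1.0)
        for i in range(3):
            corr = np.corrcoef(traj.states[:, i], ident_monthly[:61, i])[0, 1]
            assert corr >= 0.99

    def test_matches_brute_force_normal_equations_oracle(self, ident_monthly):
        """Independent dense solve of the same ridge problem."""
        data = ident_monthly
        lo, hi = data.min(axis=0), data.max(axis=0)
        center, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
        u = (data - center) / half
        du = (u[2:] - u[:-2]) / 2.0
        B = np.array([[float(np.prod(np.asarray(p) ** np.array(e)))
                       for e in pb.EXPONENTS] for p in u[1:-1]])
        # a ridge large enough to keep the normal equations well conditioned:
        # at machine precision two independently coded solvers can only agree
        # to cond(G) * eps, so the equivalence check controls cond(G)
        ridge = 1e-3
        # brute-force normal equations, assembled with explicit loops
        G = np.zeros((20, 20))
        for i in range(20):
            for j in range(20):
                G[i, j] = float(np.dot(B[:, i], B[:, j]))
            G[i, i] += ridge
        rhs = np.column_stack([B.T @ du[:, k] for k in range(3)])
        oracle_scaled = np.linalg.solve(G, rhs).T
        got_scaled, got_center, got_half = tj.derivative_regression(
            data, ridge_weight=ridge, dt=1.0)
        np.testing.assert_allclose(got_center, center, rtol=1e-14)
        np.testing.assert_allclose(got_half, half, rtol=1e-14)
        scale = np.max(np.abs(oracle_scaled))
        np.testing.assert_allclose(got_scaled, oracle_scaled, atol=1e-8 * scale)
        # and the emitted raw-unit model realizes the same vector field
        model = tj.init_coefficients(data, ridge_weight=ridge, dt=1.0)
        for p in data[::200]:
            want = (pb.basis((p - center) / half) @ oracle_scaled.T) * half
            np.testing.assert_allclose(tj.evaluate_rhs(model, p), want,
                                       atol=1e-8 * np.abs(want).max())

    def test_short_data_rejected(self):
        with pytest.raises(ValueError, match="40"):
            tj.init_coefficients(np.zeros((30, 3)) + np.arange(30)[:, None])


class TestRefine:
    def test_exact_generator_is_fixed_point(self, benchmark, ident_monthly):
        model, rep = tj.refine(benchmark, ident_monthly,
                               tj.TMConfig(optimizer_budget=80))
        assert rep.total <= 1e-6

    def test_local_convergence_from_perturbed_truth(self, benchmark, ident_monthly):
        C = benchmark.coefficients.copy()
        C[np.abs(C) > 0] *= 1.05
        start = tj.PolyODEModel(coefficients=C)
        q0 = tj.quality(start, ident_monthly).total
        refined, rep = tj.refine(start, ident_monthly,
                                 tj.TMConfig(optimizer_budget=120))
        assert rep.total <= 0.10 * q0

    def test_never_increases_quality(self, ident_monthly):
        start = tj.init_coefficients(ident_monthly, ridge_weight=1e-6)
        q0 = tj.quality(start, ident_monthly).total
        _, rep = tj.refine(start, ident_monthly, tj.TMConfig(optimizer_budget=70))
        assert rep.total <= q0


class TestIsStable:
    def test_benchmark_stable(self, benchmark, ident_monthly):
        assert tj.is_stable(benchmark, ident_monthly)

    def test_growth_model_unstable(self, ident_monthly):
        C = np.zeros((3, 20))
        C[0, _IDX[(1, 0, 0)]] = 0.05
        assert not tj.is_stable(tj.PolyODEModel(coefficients=C), ident_monthly)

    def test_zero_dynamics_stable(self, ident_monthly):
        assert tj.is_stable(tj.PolyODEModel(coefficients=np.zeros((3, 20))),
                            ident_monthly)


class TestSearch:
    def test_benchmark_recovery_period_within_5pct(self, bench_search, ident_monthly):
        from bioclimdyn import dynamics as dyn
        assert bench_search.best is not None
        model, _, _ = bench_search.best
        run = dyn.long_term(model, ident_monthly[0], steps=7000)
        period = dyn.estimate_period(run)
        assert period == pytest.approx(642.0, rel=0.05)

    def test_benchmark_active_coefficients_within_10pct(self, bench_search):
        truth_nf = sy._benchmark_normal_form()
        active = np.abs(truth_nf) > 0
        model, _, _ = bench_search.best
        nf = _normal_form(model)
        rel = np.abs(nf[active] - truth_nf[active]) / np.abs(truth_nf[active])
        assert rel.max() < 0.10

    def test_white_noise_no_crash(self):
        rng = np.random.default_rng(42)
        data = rng.normal(size=(360, 3)) * [10, 5, 1] + [125, 50, 9]
        result = tj.search(
            data, [tj.TMConfig(ridge_weight=1e-8, optimizer_budget=40)], seed=0)
        assert len(result.trial_log) == 1
        for model, rep, _cfg in result.candidates:
            assert rep.total > 1.0   # nothing that actually fits the noise

    def test_empty_grid_rejected(self, ident_monthly):
        with pytest.raises(ValueError):
            tj.search(ident_monthly, [], seed=0)

    def test_trial_log_export(self, bench_search, tmp_path):
        path = tmp_path / "log.csv"
        bench_search.export_log(path)
        import pandas as pd
        frame = pd.read_csv(path)
        assert len(frame) == 3
        assert {"ridge", "q_total", "stable"} <= set(frame.columns)


class TestSerialization:
    def test_model_json_round_trip(self, benchmark, tmp_path):
        path = tmp_path / "model.json"
        benchmark.to_json(path)
        back = tj.PolyODEModel.from_json(path)
        np.testing.assert_array_equal(back.coefficients, benchmark.coefficients)
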