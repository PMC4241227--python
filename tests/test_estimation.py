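"""Objective functions, inner solvers and the estimation front-end."""

import numpy as np
import pytest

import intflux as ifx
from intflux.errors import EstimationError
from intflux.estimation import solve_inner_ifpe, solve_inner_ipe
from intflux.fluxes import IFTable, cumulative_integral


class TestObjectives:
    def test_outer_zero_at_equality(self):
        X = np.random.default_rng(0).random((5, 3))
        assert ifx.outer_objective(X, X) == 0.0

    def test_outer_single_entry(self):
        assert ifx.outer_objective(np.array([[3.0]]), np.array([[1.0]])) == 2.0

    def test_outer_loop_oracle(self):
        rng = np.random.default_rng(1)
        A, B = rng.random((2, 4, 5))
        total = 0.0
        for k in range(4):
            for i in range(5):
                total += (A[k, i] - B[k, i]) ** 2
        assert ifx.outer_objective(A, B) == pytest.approx(
            np.sqrt(total / 20), abs=1e-12)

    def test_inner_matches_printed_normalization(self):
        t = np.array([0.0, 1.0, 2.0])
        a = IFTable(t, np.zeros((3, 1)), ["v2"])
        b = IFTable(t, np.array([[0.0], [0.0], [3.0]]), ["v2"])
        # single nonzero difference 3, m=1, K=3 -> sqrt(9/3)
        assert ifx.inner_objective(a, b, m=1) == pytest.approx(np.sqrt(3.0))

    def test_slope_objective_single_diff(self):
        assert ifx.slope_objective(np.array([[5.0]]), np.array([[0.0]])) == 5.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(EstimationError):
            ifx.outer_objective(np.ones((2, 2)), np.ones((3, 2)))


class TestParameterError:
    def test_perfect(self):
        assert ifx.parameter_error({"a": 1.0}, {"a": 1.0}) == 0.0

    def test_uniform_ten_percent(self):
        p = {"a": 1.0, "b": -2.0, "c": 4.0}
        ph = {k: 1.1 * v for k, v in p.items()}
        assert ifx.parameter_error(ph, p) == pytest.approx(10.0)

    def test_median_of_mixed_errors(self):
        assert ifx.parameter_error((1.1, 1.9, 4.0), (1.0, 2.0, 4.0)) == \
            pytest.approx(5.0)

    def test_zero_truth_rejected(self):
        with pytest.raises(EstimationError):
            ifx.parameter_error((1.0,), (0.0,))


class TestInnerIFPE:
    def test_linlog_exact_recovery(self, toy_linlog, toy_linlog_data):
        """Noise-free dependent IFs from known lin-log parameters are
        recovered exactly by the closed-form linear fit."""
        model, p_true, _ = toy_linlog
        part = ifx.make_partition(model, ["v1"])
        eta_D = ifx.predicted_dependent_if(
            model, part, toy_linlog_data,
            {nm: p_true[nm] for nm in part.p_D})
        p_D, diag = solve_inner_ifpe(model, part, toy_linlog_data, eta_D)
        for nm in part.p_D:
            assert p_D[nm] == pytest.approx(p_true[nm], abs=1e-8)

    def test_gma_constant_if_linear_fit(self, toy_gma, toy_gma_data):
        """eta(t) = c * t with kinetic order pinned at zero gives a = c."""
        model, _, _ = toy_gma
        part = ifx.make_partition(model, ["v2"])  # dependent: v1 (a only), v3
        c = 0.9
        eta = IFTable(toy_gma_data.times,
                      np.column_stack([c * toy_gma_data.times,
                                       c * toy_gma_data.times]),
                      part.dependent_names)
        p_D, _ = solve_inner_ifpe(model, part, toy_gma_data, eta, seed=0)
        assert p_D["a_v1"] == pytest.approx(c, abs=1e-8)

    def test_linlog_closed_form_equals_nonlinear_solver(self, lactis):
        """The linear-least-squares inner solution for lin-log laws matches a
        bounded trust-region nonlinear fit on random instances."""
        rng = np.random.default_rng(42)
        model = lactis
        part = ifx.make_partition(model, ["v5", "v7", "v9"])
        K = 15
        t = np.linspace(0, 10, K)
        X = rng.uniform(0.2, 3.0, (K, model.n_species))
        ds = ifx.TimeSeriesDataset(t, X, model.species_names)
        for trial in range(10):
            p_rand = {nm: rng.uniform(-3, 3) for nm in part.p_D}
            eta_D = ifx.predicted_dependent_if(model, part, ds, p_rand)
            noisy = IFTable(t, eta_D.eta + 0.05 * rng.standard_normal(eta_D.eta.shape),
                            eta_D.reaction_names)
            p_lin, _ = solve_inner_ifpe(model, part, ds, noisy)
            # independent nonlinear route per dependent reaction
            for col, (rid, rname) in enumerate(zip(part.dependent_ids,
                                                   part.dependent_names)):
                names = model.free_parameters_of([rid])

                def resid(x):
                    eta = ifx.predicted_dependent_if(
                        model, part, ds, {**{n: 0.0 for n in part.p_D},
                                          **dict(zip(names, x))})
                    return eta.eta[:, col] - noisy.eta[:, col]

                x_nl, st = ifx.bounded_least_squares(
                    resid, np.zeros(len(names)),
                    [model.bounds[n] for n in names])
                for nm, xv in zip(names, x_nl):
                    assert p_lin[nm] == pytest.approx(xv, abs=1e-6)


class TestInnerIPE:
    def test_gma_log_linear_recovery(self, toy_gma):
        """Noise-free fluxes from a known power law are recovered to 1e-8."""
        model, _, _ = toy_gma
        part = ifx.make_partition(model, ["v1"])  # dependent v2, v3
        rng = np.random.default_rng(5)
        K = 20
        X = rng.uniform(0.3, 4.0, (K, 2))
        ds = ifx.TimeSeriesDataset(np.linspace(0, 5, K), X, ["X1", "X2"])
        a2, g2, a3, g3 = 2.0, 0.5, 1.2, 0.6
        v_D = np.column_stack([a2 * X[:, 0] ** g2, a3 * X[:, 1] ** g3])
        p_D, _ = solve_inner_ipe(model, part, ds, v_D)
        assert p_D["a_v2"] == pytest.approx(a2, abs=1e-8)
        assert p_D["g_v2_X1"] == pytest.approx(g2, abs=1e-8)
        assert p_D["a_v3"] == pytest.approx(a3, abs=1e-8)
        assert p_D["g_v3_X2"] == pytest.approx(g3, abs=1e-8)

    def test_constant_flux_geometric_mean(self, toy_gma):
        """With the kinetic order fixed, the log-space fit returns the
        geometric mean of the flux values."""
        model, _, _ = toy_gma
        part = ifx.make_partition(model, ["v2"])  # dependent: v1 (a only), v3
        rng = np.random.default_rng(6)
        K = 30
        X = rng.uniform(0.5, 2.0, (K, 2))
        ds = ifx.TimeSeriesDataset(np.linspace(0, 5, K), X, ["X1", "X2"])
        v1 = rng.uniform(0.5, 2.0, K)
        v_D = np.column_stack([v1, 1.2 * X[:, 1] ** 0.6])
        p_D, _ = solve_inner_ipe(model, part, ds, v_D)
        assert p_D["a_v1"] == pytest.approx(
            np.exp(np.mean(np.log(v1))), abs=1e-8)

    def test_active_upper_bound(self):
        """Unconstrained optimum above the box lands on the boundary."""
        from intflux.models import GMARateLaw, KineticModel

        law1 = GMARateLaw(free=["a"], bounds={"a": (0.0, 1.0)})
        law2 = GMARateLaw(orders={"X1": 1.0}, free=["a"],
                          values={"g:X1": 1.0}, bounds={"a": (0, 10)})
        m = KineticModel(["X1"], ["v1", "v2"], np.array([[1.0, -1.0]]),
                         [law1, law2])
        part = ifx.make_partition(m, ["v2"])
        K = 10
        ds = ifx.TimeSeriesDataset(np.linspace(0, 1, K),
                                   np.ones((K, 1)), ["X1"])
        v_D = np.full((K, 1), 1.5)     # optimum a=1.5, bound caps at 1.0
        p_D, _ = solve_inner_ipe(m, part, ds, v_D)
        assert p_D["a_v1"] == pytest.approx(1.0, abs=1e-10)

    def test_nonpositive_fluxes_dropped(self, toy_gma):
        model, _, _ = toy_gma
        part = ifx.make_partition(model, ["v1"])
        K = 12
        rng = np.random.default_rng(7)
        X = rng.uniform(0.5, 2.0, (K, 2))
        ds = ifx.TimeSeriesDataset(np.linspace(0, 3, K), X, ["X1", "X2"])
        v_D = np.column_stack([2.0 * X[:, 0] ** 0.5, 1.2 * X[:, 1] ** 0.6])
        v_D[3, 0] = -0.2
        p_D, diag = solve_inner_ipe(model, part, ds, v_D)
        assert diag["dropped_rows"]["v2"] == 1
        assert p_D["a_v2"] == pytest.approx(2.0, rel=1e-6)


class TestLinLogLinearity:
    def test_predicted_if_affine_in_parameters(self, toy_linlog,
                                               toy_linlog_data):
        """For lin-log laws the predicted dependent IF is linear in p_D."""
        model, _, _ = toy_linlog
        part = ifx.make_partition(model, ["v1"])
        rng = np.random.default_rng(9)
        p = {nm: rng.uniform(-2, 2) for nm in part.p_D}
        q = {nm: rng.uniform(-2, 2) for nm in part.p_D}
        al, be = 0.7, -1.3

        def eta(pp):
            return ifx.predicted_dependent_if(model, part, toy_linlog_data,
                                              pp).eta

        combo = {nm: al * p[nm] + be * q[nm] for nm in part.p_D}
        assert np.allclose(eta(combo), al * eta(p) + be * eta(q)
                           + (1 - al - be) * eta({nm: 0.0 for nm in part.p_D}),
                           atol=1e-10)

    def test_inner_objective_hessian_constant(self, lactis):
        """Phi_in is exactly quadratic in p_D for lin-log models: its
        numerical Hessian is the same at random points."""
        model = lactis
        part = ifx.make_partition(model, ["v5", "v7", "v9"])
        rng = np.random.default_rng(13)
        K = 12
        ds = ifx.TimeSeriesDataset(
            np.linspace(0, 8, K), rng.uniform(0.2, 3.0, (K, 9)),
            model.species_names)
        target = IFTable(ds.times,
                         rng.standard_normal((K, len(part.dependent_ids))),
                         part.dependent_names)

        names = part.p_D

        def phi_sq(x):
            eta = ifx.predicted_dependent_if(model, part, ds,
                                             dict(zip(names, x)))
            d = eta.eta - target.eta
            return float(np.sum(d * d))

        def hessian_at(x0, h=1e-3):
            n = len(x0)
            H = np.empty((n, n))
            for i in range(n):
                for j in range(n):
                    ei = np.eye(n)[i] * h
                    ej = np.eye(n)[j] * h
                    H[i, j] = (phi_sq(x0 + ei + ej) - phi_sq(x0 + ei - ej)
                               - phi_sq(x0 - ei + ej) + phi_sq(x0 - ei - ej)
                               ) / (4 * h * h)
            return H

        x1 = rng.uniform(-5, 5, len(names))
        x2 = rng.uniform(-5, 5, len(names))
        H1, H2 = hessian_at(x1), hessian_at(x2)
        assert np.allclose(H1, H2, rtol=1e-4, atol=1e-4)


class TestEstimateFrontEnd:
    def test_unknown_method_rejected(self, toy_gma, toy_gma_data):
        model, _, _ = toy_gma
        with pytest.raises(EstimationError, match="foo"):
            ifx.estimate("foo", model, toy_gma_data)

    def test_missing_partition_rejected(self, toy_gma, toy_gma_data):
        model, _, _ = toy_gma
        with pytest.raises(EstimationError, match="partition"):
            ifx.estimate("ifpe", model, toy_gma_data)

    def test_missing_spline_rejected(self, toy_gma, toy_gma_data):
        model, _, _ = toy_gma
        part = ifx.make_partition(model, ["v1"])
        with pytest.raises(EstimationError, match="spline"):
            ifx.estimate("ipe-slope", model, toy_gma_data, partition=part)

    def test_spe_ode_one_parameter_grid_search_oracle(self):
        """SPE-ODE on exponential decay matches a dense grid search."""
        from intflux.models import GMARateLaw, KineticModel

        law = GMARateLaw(orders={"X1": 1.0}, free=["a"],
                         values={"g:X1": 1.0}, bounds={"a": (0.1, 5.0)})
        m = KineticModel(["X1"], ["v1"], np.array([[-1.0]]), [law])
        t = np.linspace(0, 2, 15)
        data = ifx.TimeSeriesDataset(t, np.exp(-0.7 * t)[:, None], ["X1"])

        grid = np.linspace(0.1, 5.0, 10 ** 4)
        phis = [ifx.outer_objective(np.exp(-k * t)[:, None], data.values)
                for k in grid]
        k_grid = grid[int(np.argmin(phis))]

        res = ifx.estimate(
            "spe-ode", m, data, seed=4,
            optimizer=ifx.OptimizerConfig(bounds=[(0, 1)], max_iterations=150))
        assert res.parameters["a_v1"] == pytest.approx(
            k_grid, abs=(5.0 - 0.1) / 10 ** 4 + 1e-4)

    def test_ifpe_and_ifpe_ode_agree_at_truth(self, branched, branched_data):
        """Both IFPE objective variants are small (quadrature/integration
        tolerance) at the true independent parameters."""
        from intflux.estimation import _NestedObjective

        model, p_true, _ = branched
        part = ifx.make_partition(model, ["v1", "v6"])
        p_I = np.array([p_true[nm] for nm in part.p_I])
        phi = _NestedObjective("ifpe", model, part, branched_data,
                               None, 0, {})(p_I)
        phi_ode = _NestedObjective("ifpe-ode", model, part, branched_data,
                                   None, 0, {})(p_I)
        assert phi < 1e-2 and phi_ode < 1e-2
        assert abs(phi - phi_ode) < 1e-2

    @pytest.mark.parametrize("method", ["ipe-ode", "spe-slope"])
    def test_smoothing_methods_run_end_to_end(self, method, toy_gma,
                                              toy_gma_data):
        """The ODE-scored incremental variant and the slope-scored
        simultaneous variant produce finite objectives and in-bounds
        parameters on the toy."""
        model, _, _ = toy_gma
        part = ifx.make_partition(model, ["v1"])
        res = ifx.estimate(
            method, model, toy_gma_data, partition=part, spline=(3, 3),
            seed=2, optimizer=ifx.OptimizerConfig(
                bounds=[(0, 1)], max_iterations=15, stagnation_window=8))
        assert np.isfinite(res.objective)
        for nm, v in res.parameters.items():
            lo, hi = model.bounds[nm]
            assert lo - 1e-9 <= v <= hi + 1e-9

    def test_replicate_summary(self, toy_gma):
        model, p_true, X0 = toy_gma
        t = np.linspace(0, 8, 40)
        reps = ifx.generate_dataset(model, p_true, X0, t,
                                    noise_cfg={"cv": 0.1, "replicates": 3},
                                    seed=8)
        part = ifx.make_partition(model, ["v1"])
        out = ifx.estimate(
            "ifpe", model, reps, partition=part, seed=5,
            optimizer=ifx.OptimizerConfig(bounds=[(0, 1)], max_iterations=40,
                                          stagnation_window=15))
        assert isinstance(out, ifx.ReplicateSummary)
        assert len(out.results) == 3
        assert out.mean_error_pct is not None and out.sd_error_pct >= 0
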