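"""Nested and simultaneous parameter estimation for kinetic models.

Six methods are provided:

* ``ifpe`` / ``ifpe-ode`` — integrated-flux parameter estimation.  The
  outer search runs over the independent parameters ``p_I``; for each
  candidate, the independent IFs are integrated from data (measured
  concentrations, no smoothing), the dependent IFs follow algebraically
  from the mass balance, the dependent parameters ``p_D`` are fitted one
  reaction at a time to those IFs, and the concentration prediction comes
  either from the integral form (``ifpe``) or from ODE simulation
  (``ifpe-ode``).
* ``ipe-slope`` / ``ipe-ode`` — incremental estimation from smoothed-data
  derivatives: dependent flux values are solved from spline slopes, the
  inner fit regresses rate laws on those flux values, and the outer
  objective is the slope error (``ipe-slope``) or the simulated
  concentration error (``ipe-ode``).
* ``spe-slope`` / ``spe-ode`` — simultaneous estimation over all free
  parameters with the slope or concentration objective.

All objectives share the root-mean-square form over the ``m x K`` data
matrix.  Candidates producing negative fluxes or integrated fluxes incur
an additive penalty (positivity constraint) instead of hard rejection.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares, lsq_linear

from . import fluxes as fx
from .errors import AlignmentError, DomainError, EstimationError, SimulationError
from .models import FluxPartition, KineticModel
from .optimize import (SENTINEL, OptimizerConfig, OptimizerTrace,
                       global_minimize)
from .simulate import simulate
from .timeseries import (SplineFit, TimeSeriesDataset, fit_spline,
                         interpolate_missing, spline_deriv, spline_eval)

log = logging.getLogger(__name__)

__all__ = [
    "EstimationResult", "ReplicateSummary",
    "outer_objective", "inner_objective", "slope_objective",
    "solve_inner_ifpe", "solve_inner_ipe",
    "estimate", "parameter_error", "METHODS",
]

METHODS = ("ifpe", "ifpe-ode", "ipe-slope", "ipe-ode", "spe-slope", "spe-ode")

#: additive penalty per positivity violation (negative flux or IF value)
POSITIVITY_PENALTY = 1e6


# --------------------------------------------------------------------- #
# objectives
# --------------------------------------------------------------------- #
def _rmse(A: np.ndarray, B: np.ndarray, denom: int | None = None) -> float:
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise EstimationError(f"shape mismatch {A.shape} vs {B.shape}")
    d = A - B
    n = denom if denom is not None else d.size
    return float(np.sqrt(np.sum(d * d) / n))


def outer_objective(X_pred: np.ndarray, X_meas: np.ndarray) -> float:
    """Concentration-prediction error: RMS deviation over all m*K entries."""
    return _rmse(X_pred, X_meas)


def inner_objective(eta_pred: fx.IFTable, eta_data: fx.IFTable,
                    m: int) -> float:
    """Dependent-IF prediction error, normalized by ``m * K`` with ``m`` the
    species count (as printed; a constant factor that does not move the
    argmin)."""
    if eta_pred.eta.shape != eta_data.eta.shape:
        raise AlignmentError("IF tables are not aligned")
    if not np.allclose(eta_pred.times, eta_data.times, rtol=0, atol=1e-12):
        raise AlignmentError("IF tables are on different time grids")
    return _rmse(eta_pred.eta, eta_data.eta, denom=m * eta_pred.times.size)


def slope_objective(dX_pred: np.ndarray, dX_meas: np.ndarray) -> float:
    """Slope-prediction error: RMS deviation between predicted and
    spline-estimated concentration derivatives."""
    return _rmse(dX_pred, dX_meas)


def parameter_error(p_hat: Mapping[str, float] | Sequence[float],
                    p_true: Mapping[str, float] | Sequence[float]) -> float:
    """Median relative parameter error in percent,
    ``median_i 100 |p_hat_i - p_true_i| / |p_true_i|``."""
    if isinstance(p_hat, Mapping) and isinstance(p_true, Mapping):
        keys = list(p_true)
        missing = [k for k in keys if k not in p_hat]
        if missing:
            raise EstimationError(f"estimates missing parameters {missing}")
        ph = np.array([float(p_hat[k]) for k in keys])
        pt = np.array([float(p_true[k]) for k in keys])
    else:
        ph = np.asarray(p_hat, dtype=float)
        pt = np.asarray(p_true, dtype=float)
        if ph.shape != pt.shape:
            raise EstimationError("parameter vectors differ in length")
    if np.any(pt == 0):
        raise EstimationError("relative error undefined: true parameter equals 0")
    return float(np.median(100.0 * np.abs(ph - pt) / np.abs(pt)))


# --------------------------------------------------------------------- #
# inner solvers
# --------------------------------------------------------------------- #
def _log_concentration_integrals(dataset: TimeSeriesDataset,
                                 species: Sequence[str]) -> np.ndarray:
    """Cumulative integrals of ln X_i on the measurement grid, (K, len)."""
    lnX = np.column_stack([np.log(dataset.column(s)) for s in species])
    if not np.all(np.isfinite(lnX)):
        raise DomainError("non-positive concentration: cannot integrate ln X")
    return fx.cumulative_integral(dataset.times, lnX)


def solve_inner_ifpe(
    model: KineticModel,
    partition: FluxPartition,
    dataset: TimeSeriesDataset,
    eta_D_data: fx.IFTable,
    seed: int | None = None,
    n_starts: int = 5,
    warm: dict | None = None,
) -> tuple[dict[str, float], dict]:
    """Fit dependent parameters to the data-derived dependent IFs,
    one reaction at a time.

    Lin-log laws are linear in their parameters, so the predicted IF is a
    design matrix (columns: elapsed time and the pre-computed integrals of
    ln X_i) times the parameter vector — solved by bounded linear least
    squares.  Power-law (GMA) laws use bounded trust-region nonlinear least
    squares from a multi-start (box midpoint + seeded Latin-hypercube
    draws).

    ``warm``, when supplied, is a mutable per-reaction cache of previous
    solutions: after the first full multi-start, later calls (successive
    outer-optimizer candidates) start from the cached optimum plus the
    box midpoint, tracking the smoothly moving inner optimum at a
    fraction of the cost.
    """
    rng = np.random.default_rng(seed)
    p_D: dict[str, float] = {}
    diag = {"inner_status": {}, "failed": False}
    fixed = model.fixed_parameters()
    t_rel = fx.cumulative_integral(
        dataset.times, np.ones_like(dataset.times))  # elapsed time since t_0

    for col, (rid, rname) in enumerate(
            zip(partition.dependent_ids, partition.dependent_names)):
        law = model.rate_laws[rid]
        names = model.free_parameters_of([rid])
        if not names:
            continue
        target = eta_D_data.eta[:, col]
        lo = np.array([model.bounds[nm][0] for nm in names])
        hi = np.array([model.bounds[nm][1] for nm in names])

        if law.family == "linlog":
            cols = []
            for nm in names:
                _, role, sp = model.parameter_index[nm]
                if role == "a":
                    cols.append(t_rel)
                else:
                    cols.append(_log_concentration_integrals(dataset, [sp])[:, 0])
            A = np.column_stack(cols)
            # fixed-parameter contribution moves to the target side
            offset = np.zeros_like(target)
            a_fix = fixed.get(f"a_{rname}")
            if a_fix is not None:
                offset += a_fix * t_rel
            for sp in law.orders:
                g_fix = fixed.get(f"g_{rname}_{sp}")
                if g_fix is not None:
                    offset += g_fix * _log_concentration_integrals(dataset, [sp])[:, 0]
            res = lsq_linear(A, target - offset, bounds=(lo, hi))
            sol = res.x
            diag["inner_status"][rname] = {"converged": bool(res.success),
                                           "cost": float(res.cost)}
        else:
            # fast GMA path: v = a * exp(lnX @ g), eta = W v is smooth in
            # (a, g) with closed-form Jacobian
            W = fx.cumulative_weights(dataset.times)
            roles = [model.parameter_index[nm][1:] for nm in names]
            g_species = [sp for role, sp in roles if role == "g"]
            lnXs = (np.column_stack(
                [np.log(dataset.column(sp)) for sp in g_species])
                if g_species else np.zeros((dataset.K, 0)))
            if not np.all(np.isfinite(lnXs)):
                raise DomainError(
                    f"non-positive concentration in reaction {rname} power fit")
            fixed_ln = 0.0
            a_fixed = fixed.get(f"a_{rname}")
            for sp in law.orders:
                gf = fixed.get(f"g_{rname}_{sp}")
                if gf is not None:
                    fixed_ln = fixed_ln + gf * np.log(dataset.column(sp))
            a_pos = 0 if roles and roles[0][0] == "a" else None

            def split(x):
                if a_pos is None:
                    a = a_fixed
                    g = x
                else:
                    a, g = x[0], x[1:]
                return a, g

            def v_of(x):
                a, g = split(x)
                return a * np.exp(lnXs @ g + fixed_ln)

            def residual(x):
                return W @ v_of(x) - target

            def jacobian(x):
                a, g = split(x)
                core = np.exp(lnXs @ g + fixed_ln)
                cols = []
                if a_pos is not None:
                    cols.append(core)
                for i in range(lnXs.shape[1]):
                    cols.append(a * core * lnXs[:, i])
                return W @ np.column_stack(cols)

            if warm is not None and rname in warm:
                x0s = [warm[rname], 0.5 * (lo + hi)]
            else:
                x0s = [0.5 * (lo + hi)]
                if n_starts > 1:
                    strata = (np.argsort(rng.random((n_starts - 1, lo.size)),
                                         axis=0)
                              + rng.random((n_starts - 1, lo.size))) / (n_starts - 1)
                    x0s.extend(lo + strata * (hi - lo))
            best = None
            for x0 in x0s:
                res = least_squares(residual, np.clip(x0, lo, hi), jac=jacobian,
                                    bounds=(lo, hi), method="trf")
                status = {"converged": bool(res.success),
                          "status": int(res.status),
                          "cost": float(res.cost), "nfev": int(res.nfev)}
                if best is None or status["cost"] < best[1]["cost"]:
                    best = (res.x, status)
            sol, status = best
            if warm is not None:
                warm[rname] = np.asarray(sol, dtype=float)
            diag["inner_status"][rname] = status
        p_D.update(zip(names, sol))
    return p_D, diag


def solve_inner_ipe(
    model: KineticModel,
    partition: FluxPartition,
    dataset: TimeSeriesDataset,
    v_D_values: np.ndarray,
    X_at_times: np.ndarray | None = None,
) -> tuple[dict[str, float], dict]:
    """Fit dependent parameters to slope-based flux values, one reaction at
    a time, as bounded *linear* least squares.

    GMA laws are log-transformed (``ln v = ln a + sum g ln X``); rows with
    non-positive flux estimates are dropped with a logged count.  Lin-log
    laws regress directly on ``(1, ln X_i)``.  ``X_at_times`` supplies the
    concentrations to regress on (default: the measured values).
    """
    p_D: dict[str, float] = {}
    diag = {"inner_status": {}, "dropped_rows": {}, "failed": False}
    if X_at_times is None:
        X_at_times = np.column_stack(
            [dataset.column(s) for s in model.species_names])
    lnX_all = None

    for col, (rid, rname) in enumerate(
            zip(partition.dependent_ids, partition.dependent_names)):
        law = model.rate_laws[rid]
        names = model.free_parameters_of([rid])
        if not names:
            continue
        v = v_D_values[:, col]
        lo = np.array([model.bounds[nm][0] for nm in names])
        hi = np.array([model.bounds[nm][1] for nm in names])
        fixed = model.fixed_parameters()

        if law.family == "gma":
            keep = v > 0
            dropped = int(np.sum(~keep))
            if dropped:
                log.debug("reaction %s: dropped %d non-positive flux values "
                          "before log-linear fit", rname, dropped)
                diag["dropped_rows"][rname] = dropped
            if not np.any(keep):
                diag["failed"] = True
                diag["inner_status"][rname] = {"converged": False,
                                               "reason": "all fluxes non-positive"}
                continue
            y = np.log(v[keep])
            cols, lob, hib = [], [], []
            for nm, l, h in zip(names, lo, hi):
                _, role, sp = model.parameter_index[nm]
                if role == "a":
                    cols.append(np.ones(int(keep.sum())))
                    lob.append(np.log(max(l, 1e-300)) if l > 0 else -np.inf)
                    hib.append(np.log(h) if np.isfinite(h) else np.inf)
                else:
                    xs = X_at_times[keep, model.species_index(sp)]
                    if np.any(xs <= 0):
                        raise DomainError(
                            f"non-positive concentration of {sp} in log fit")
                    cols.append(np.log(xs))
                    lob.append(l)
                    hib.append(h)
            # fixed contributions to ln v
            a_fix = fixed.get(f"a_{rname}")
            if a_fix is not None:
                y = y - np.log(a_fix)
            for sp in law.orders:
                g_fix = fixed.get(f"g_{rname}_{sp}")
                if g_fix is not None:
                    y = y - g_fix * np.log(X_at_times[keep, model.species_index(sp)])
            A = np.column_stack(cols)
            res = lsq_linear(A, y, bounds=(np.array(lob), np.array(hib)))
            sol = res.x.copy()
            for i, nm in enumerate(names):
                if model.parameter_index[nm][1] == "a":
                    sol[i] = np.exp(sol[i])
                    sol[i] = min(max(sol[i], model.bounds[nm][0]),
                                 model.bounds[nm][1])
        else:  # linlog: already linear
            if lnX_all is None:
                with np.errstate(invalid="raise", divide="raise"):
                    try:
                        lnX_all = np.log(X_at_times)
                    except FloatingPointError:
                        raise DomainError(
                            "non-positive concentration in lin-log fit") from None
            cols = []
            for nm in names:
                _, role, sp = model.parameter_index[nm]
                cols.append(np.ones(v.size) if role == "a"
                            else lnX_all[:, model.species_index(sp)])
            y = v.astype(float).copy()
            a_fix = fixed.get(f"a_{rname}")
            if a_fix is not None:
                y -= a_fix
            for sp in law.orders:
                g_fix = fixed.get(f"g_{rname}_{sp}")
                if g_fix is not None:
                    y -= g_fix * lnX_all[:, model.species_index(sp)]
            A = np.column_stack(cols)
            res = lsq_linear(A, y, bounds=(lo, hi))
            sol = res.x
        diag["inner_status"][rname] = {"converged": bool(res.success),
                                       "cost": float(res.cost)}
        p_D.update(zip(names, sol))
    return p_D, diag


# --------------------------------------------------------------------- #
# estimation result containers
# --------------------------------------------------------------------- #
@dataclass
class EstimationResult:
    """Outcome of one estimation run on one dataset."""

    method: str
    parameters: dict[str, float]
    objective: float
    trace: OptimizerTrace
    partition: FluxPartition | None
    wall_time: float
    seed: int | None
    diagnostics: dict = field(default_factory=dict)
    replicate_id: str | None = None
    median_rel_error_pct: float | None = None

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "seed": self.seed,
            "objective": self.objective,
            "parameters": self.parameters,
            "median_rel_error_pct": self.median_rel_error_pct,
            "wall_time_s": self.wall_time,
            "replicate_id": self.replicate_id,
            "partition": (self.partition.independent_names
                          if self.partition else None),
            "iterations": len(self.trace.iterations) - 1 if self.trace else None,
            "diagnostics": {k: v for k, v in self.diagnostics.items()
                            if k != "inner_status"},
        }


@dataclass
class ReplicateSummary:
    """Independent fits of technical replicates, summarized as mean +/- sd
    of the error metric (and of the objective)."""

    results: list[EstimationResult]

    @property
    def mean_error_pct(self) -> float | None:
        errs = [r.median_rel_error_pct for r in self.results]
        if any(e is None for e in errs):
            return None
        return float(np.mean(errs))

    @property
    def sd_error_pct(self) -> float | None:
        errs = [r.median_rel_error_pct for r in self.results]
        if any(e is None for e in errs):
            return None
        return float(np.std(errs, ddof=1)) if len(errs) > 1 else 0.0


# --------------------------------------------------------------------- #
# the estimator
# --------------------------------------------------------------------- #
def _count_negative(*arrays: np.ndarray, tol: float = 0.0) -> int:
    return int(sum(np.sum(a < -tol) for a in arrays))


class _NestedObjective:
    """Outer objective for the nested (ifpe*/ipe*) methods."""

    def __init__(self, method: str, model: KineticModel,
                 partition: FluxPartition, dataset: TimeSeriesDataset,
                 spline_fits: SplineFit | None, seed: int | None,
                 sim_kwargs: dict):
        self.method = method
        self.model = model
        self.partition = partition
        self.dataset = dataset
        self.spline_fits = spline_fits
        self.seed = seed
        self.sim_kwargs = sim_kwargs
        self.X_meas = np.column_stack(
            [dataset.column(s) for s in model.balanced_species])
        self.X0 = self.X_meas[0]
        self.violations = 0
        self.last_p_D: dict[str, float] = {}
        self._warm: dict = {}
        if spline_fits is not None:
            self.dX_spline = spline_deriv(spline_fits, dataset.times)
            bal_idx = [spline_fits.species_names.index(s)
                       for s in model.balanced_species]
            self.dX_spline = self.dX_spline[:, bal_idx]

    def offline_inputs(self):
        if not self.model.offline_species:
            return None
        if self.spline_fits is None:
            raise EstimationError(
                "offline species require spline fits for input trajectories")
        fits = self.spline_fits

        def make(sp):
            j = fits.species_names.index(sp)
            return lambda t: float(fits.splines[j](np.clip(t, fits.t_min, fits.t_max)))

        return {sp: make(sp) for sp in self.model.offline_species}

    def __call__(self, p_I_vec: np.ndarray) -> float:
        try:
            return self._evaluate(p_I_vec)
        except (DomainError, SimulationError):
            return SENTINEL

    def _evaluate(self, p_I_vec: np.ndarray) -> float:
        model, part, ds = self.model, self.partition, self.dataset
        p_I = dict(zip(part.p_I, p_I_vec))
        penalty = 0

        if self.method.startswith("ifpe"):
            eta_I = fx.independent_if(model, part, ds, p_I)
            penalty += _count_negative(eta_I.eta)
            eta_D_data = fx.dependent_if_from_data(part, ds, eta_I)
            penalty += _count_negative(eta_D_data.eta)
            p_D, diag = solve_inner_ifpe(model, part, ds, eta_D_data,
                                         seed=self.seed, warm=self._warm)
            if diag.get("failed"):
                return SENTINEL
            self.last_p_D = p_D
            full = dict(p_I)
            full.update(p_D)
            if self.method == "ifpe":
                eta_D_pred = fx.predicted_dependent_if(model, part, ds, p_D)
                penalty += _count_negative(eta_D_pred.eta)
                eta_full = fx.IFTable(
                    ds.times, part.assemble(eta_I.eta, eta_D_pred.eta),
                    list(model.reaction_names))
                X_pred = fx.reconstruct_concentrations(model, self.X0, eta_full)
            else:
                sim = simulate(model, full, self.X0, ds.times,
                               inputs=self.offline_inputs(), **self.sim_kwargs)
                X_pred = sim.trajectories
            phi = outer_objective(X_pred, self.X_meas)
        else:  # ipe-slope / ipe-ode
            v_D = fx.slope_fluxes(part, self.spline_fits, model, p_I, ds.times)
            penalty += _count_negative(v_D)
            X_sm = spline_eval(self.spline_fits, ds.times)
            order = [self.spline_fits.species_names.index(s)
                     for s in model.species_names]
            p_D, diag = solve_inner_ipe(model, part, ds, v_D,
                                        X_at_times=X_sm[:, order])
            if diag.get("failed"):
                return SENTINEL
            self.last_p_D = p_D
            full = dict(p_I)
            full.update(p_D)
            if self.method == "ipe-slope":
                params = model.full_parameter_dict(full)
                v_all = model.rates_matrix(X_sm[:, order], params)
                penalty += _count_negative(v_all)
                dX_pred = (model.S @ v_all.T).T
                phi = slope_objective(dX_pred, self.dX_spline)
            else:
                sim = simulate(model, full, self.X0, ds.times,
                               inputs=self.offline_inputs(), **self.sim_kwargs)
                phi = outer_objective(sim.trajectories, self.X_meas)
        self.violations = max(self.violations, 0)
        if penalty:
            self.violations += penalty
        return phi + POSITIVITY_PENALTY * penalty


class _SimultaneousObjective:
    """Outer objective for spe-slope / spe-ode over all free parameters."""

    def __init__(self, method, model, dataset, spline_fits, sim_kwargs):
        self.method = method
        self.model = model
        self.dataset = dataset
        self.spline_fits = spline_fits
        self.sim_kwargs = sim_kwargs
        self.X_meas = np.column_stack(
            [dataset.column(s) for s in model.balanced_species])
        self.X0 = self.X_meas[0]
        self.violations = 0
        if spline_fits is not None:
            dX = spline_deriv(spline_fits, dataset.times)
            bal_idx = [spline_fits.species_names.index(s)
                       for s in model.balanced_species]
            self.dX_spline = dX[:, bal_idx]
            Xs = spline_eval(spline_fits, dataset.times)
            order = [spline_fits.species_names.index(s)
                     for s in model.species_names]
            self.X_sm = Xs[:, order]

    def offline_inputs(self):
        return _NestedObjective.offline_inputs(self)  # same logic

    def __call__(self, p_vec: np.ndarray) -> float:
        model = self.model
        try:
            if self.method == "spe-slope":
                params = model.full_parameter_dict(p_vec)
                v_all = model.rates_matrix(self.X_sm, params)
                penalty = _count_negative(v_all)
                dX_pred = (model.S @ v_all.T).T
                phi = slope_objective(dX_pred, self.dX_spline)
            else:
                sim = simulate(model, np.asarray(p_vec), self.X0,
                               self.dataset.times,
                               inputs=self.offline_inputs(), **self.sim_kwargs)
                penalty = 0
                phi = outer_objective(sim.trajectories, self.X_meas)
        except (DomainError, SimulationError, EstimationError):
            return SENTINEL
        self.violations += penalty
        return phi + POSITIVITY_PENALTY * penalty


def estimate(
    method: str,
    model: KineticModel,
    dataset: TimeSeriesDataset | Sequence[TimeSeriesDataset],
    partition: FluxPartition | None = None,
    optimizer: OptimizerConfig | None = None,
    spline: tuple[int, int] | None = None,
    seed: int | None = None,
    p_true: Mapping[str, float] | None = None,
    sim_kwargs: dict | None = None,
) -> EstimationResult | ReplicateSummary:
    """Run one estimation method on one dataset or a list of replicates.

    ``spline`` is the ``(s, o)`` smoothing setting (required by the ipe*
    and spe-slope paths, and for offline-species inputs).  When ``dataset``
    is a list, each replicate is fitted independently and the results are
    summarized as mean +/- sd of the error metric.  ``p_true`` (or the
    model config's truth values) enables the median-relative-error metric.
    """
    if method not in METHODS:
        raise EstimationError(
            f"unknown method {method!r}; choose one of {METHODS}")
    if isinstance(dataset, (list, tuple)):
        results = [
            estimate(method, model, ds, partition=partition,
                     optimizer=optimizer, spline=spline,
                     seed=None if seed is None else seed + i,
                     p_true=p_true, sim_kwargs=sim_kwargs)
            for i, ds in enumerate(dataset)]
        return ReplicateSummary(results)  # type: ignore[arg-type]

    needs_partition = method.startswith(("ifpe", "ipe"))
    if needs_partition and partition is None:
        raise EstimationError(f"method {method!r} requires a flux partition")
    needs_spline = method.startswith("ipe") or method == "spe-slope" \
        or bool(model.offline_species)
    spline_fits = None
    if needs_spline:
        if spline is None:
            raise EstimationError(
                f"method {method!r} (or offline species) requires a spline "
                "(s, o) setting")
        ds_c = dataset if dataset.complete else interpolate_missing(dataset)
        spline_fits = fit_spline(ds_c, *spline)
    if not dataset.complete:
        dataset = interpolate_missing(dataset)
    if p_true is None:
        p_true = model.true_parameters()

    sim_kwargs = dict(sim_kwargs or {})
    t_start = time.perf_counter()

    if needs_partition:
        obj = _NestedObjective(method, model, partition, dataset,
                               spline_fits, seed, sim_kwargs)
        bounds = [model.bounds[nm] for nm in partition.p_I]
        cfg = _with_bounds(optimizer, bounds, seed)
        x, fval, trace = global_minimize(obj, cfg)
        # re-evaluate at the incumbent so last_p_D matches x
        fval = obj(x)
        p_full = dict(zip(partition.p_I, x))
        p_full.update(obj.last_p_D)
        diagnostics = {"positivity_violations": obj.violations}
    else:
        obj = _SimultaneousObjective(method, model, dataset, spline_fits,
                                     sim_kwargs)
        names = model.free_parameter_names
        bounds = [model.bounds[nm] for nm in names]
        cfg = _with_bounds(optimizer, bounds, seed)
        x, fval, trace = global_minimize(obj, cfg)
        p_full = dict(zip(names, x))
        diagnostics = {"positivity_violations": obj.violations}

    wall = time.perf_counter() - t_start
    result = EstimationResult(
        method=method, parameters=p_full, objective=float(fval),
        trace=trace, partition=partition if needs_partition else None,
        wall_time=wall, seed=seed, diagnostics=diagnostics,
        replicate_id=dataset.replicate_id)
    if p_true is not None:
        try:
            result.median_rel_error_pct = parameter_error(p_full, p_true)
        except EstimationError:
            pass
    return result


def _with_bounds(optimizer: OptimizerConfig | None,
                 bounds: list[tuple[float, float]],
                 seed: int | None) -> OptimizerConfig:
    if optimizer is None:
        return OptimizerConfig(bounds=bounds, seed=seed)
    kw = {f: getattr(optimizer, f) for f in (
        "population_size", "rel_tol", "stagnation_window", "max_iterations",
        "max_evaluations", "ref_size", "local_every", "local_budget")}
    return OptimizerConfig(bounds=bounds, seed=seed if seed is not None
                           else optimizer.seed, **kw)
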