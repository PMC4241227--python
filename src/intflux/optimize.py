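"""Bounded global and local optimization.

The outer search is a compact scatter-search-style metaheuristic: a diverse
seeded population, a reference set of elite + diverse members, pairwise
combination steps, and periodic gradient-based polish of the incumbent.
It terminates on the stagnation rule used throughout this package —
relative best-so-far improvement below ``rel_tol`` for ``stagnation_window``
successive iterations — or on iteration/evaluation budgets.

The inner (local) solver contract is bounded nonlinear least squares,
delegated to scipy's trust-region reflective implementation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares, minimize

log = logging.getLogger(__name__)

__all__ = ["OptimizerConfig", "OptimizerTrace", "global_minimize",
           "bounded_least_squares"]

#: sentinel objective for failed/penalized evaluations
SENTINEL = 1e300


@dataclass
class OptimizerConfig:
    """Settings for :func:`global_minimize`.

    ``population_size`` defaults to ``10 * dim`` (population scales linearly
    with search-space dimension).  The stagnation rule stops the search when
    the relative improvement of the best objective stays below ``rel_tol``
    for ``stagnation_window`` successive iterations.
    """

    bounds: Sequence[tuple[float, float]] = ()
    population_size: int | None = None
    rel_tol: float = 1e-5
    stagnation_window: int = 50
    max_iterations: int = 1000
    max_evaluations: int = 1_000_000
    seed: int | None = None
    ref_size: int | None = None
    local_every: int = 10
    local_budget: int = 10

    def __post_init__(self) -> None:
        b = np.asarray(self.bounds, dtype=float)
        if b.ndim != 2 or b.shape[1] != 2:
            raise ValueError("bounds must be a sequence of (lower, upper) pairs")
        if not np.all(np.isfinite(b)):
            raise ValueError("bounds must be finite")
        if not np.all(b[:, 0] < b[:, 1]):
            raise ValueError("each lower bound must be below its upper bound")
        if self.rel_tol <= 0:
            raise ValueError("rel_tol must be positive")
        self._lb = b[:, 0]
        self._ub = b[:, 1]

    @property
    def dim(self) -> int:
        return self._lb.size


@dataclass
class OptimizerTrace:
    """Best-so-far objective per iteration plus evaluation counts."""

    iterations: list[int] = field(default_factory=list)
    evaluations: list[int] = field(default_factory=list)
    best_f: list[float] = field(default_factory=list)

    def record(self, it: int, evals: int, f: float) -> None:
        self.iterations.append(it)
        self.evaluations.append(evals)
        self.best_f.append(f)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({
            "iteration": self.iterations,
            "evaluations": self.evaluations,
            "best_objective": self.best_f,
        }).to_csv(path, index=False)


def global_minimize(
    f: Callable[[np.ndarray], float],
    config: OptimizerConfig,
) -> tuple[np.ndarray, float, OptimizerTrace]:
    """Minimize ``f`` over the bounded box in ``config``.

    Exceptions raised by ``f`` and non-finite returns are captured and
    treated as the sentinel (worst) objective.  Returns the incumbent,
    its objective and the best-so-far trace.  Identical seeds give
    identical traces.
    """
    lb, ub = config._lb, config._ub
    d = config.dim
    rng = np.random.default_rng(config.seed)
    n_evals = 0

    def safe_f(x: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        try:
            val = float(f(np.clip(x, lb, ub)))
        except Exception:  # noqa: BLE001 - contract: failures become sentinel
            return SENTINEL
        return val if np.isfinite(val) else SENTINEL

    pop_size = config.population_size or 10 * d
    ref_size = config.ref_size or max(6, min(pop_size, d + 4))

    # diverse seeded population: Latin-hypercube style stratified draws
    strata = (np.argsort(rng.random((pop_size, d)), axis=0)
              + rng.random((pop_size, d))) / pop_size
    pop = lb + strata * (ub - lb)
    pop[0] = 0.5 * (lb + ub)      # always include the box midpoint
    fvals = np.array([safe_f(x) for x in pop])

    order = np.argsort(fvals, kind="stable")
    n_elite = max(ref_size // 2, 1)
    elite = list(order[:n_elite])
    rest = [i for i in order[n_elite:]]
    # diverse half: greedy max-min distance among the remainder
    diverse: list[int] = []
    scale = ub - lb
    while rest and len(elite) + len(diverse) < ref_size:
        chosen = elite + diverse
        dists = [min(np.linalg.norm((pop[i] - pop[c]) / scale) for c in chosen)
                 for i in rest]
        pick = rest.pop(int(np.argmax(dists)))
        diverse.append(pick)
    ref_idx = elite + diverse
    ref_x = pop[ref_idx].copy()
    ref_f = fvals[ref_idx].copy()

    best_i = int(np.argmin(ref_f))
    best_x, best_f = ref_x[best_i].copy(), float(ref_f[best_i])
    trace = OptimizerTrace()
    trace.record(0, n_evals, best_f)

    stagnant = 0
    it = 0
    while it < config.max_iterations and n_evals < config.max_evaluations:
        it += 1
        prev_best = best_f
        nref = ref_x.shape[0]
        # combination step: each refset member pairs with a random partner
        for i in range(nref):
            j = int(rng.integers(nref - 1))
            j = j + 1 if j >= i else j
            lam = rng.uniform(-0.5, 1.5)
            child = np.clip(ref_x[i] + lam * (ref_x[j] - ref_x[i]), lb, ub)
            fc = safe_f(child)
            worst = int(np.argmax(ref_f))
            if fc < ref_f[worst]:
                ref_x[worst] = child
                ref_f[worst] = fc
            if fc < best_f:
                best_x, best_f = child.copy(), fc

        # periodic local polish from the incumbent; Powell is derivative-free,
        # so penalty cliffs in the objective do not corrupt the search
        if config.local_every and it % config.local_every == 0 and best_f < SENTINEL:
            res = minimize(
                safe_f, best_x, method="Powell",
                bounds=list(zip(lb, ub)),
                options={"maxiter": config.local_budget})
            if np.isfinite(res.fun) and res.fun < best_f:
                best_x = np.clip(res.x, lb, ub)
                best_f = float(res.fun)
                worst = int(np.argmax(ref_f))
                ref_x[worst] = best_x
                ref_f[worst] = best_f

        trace.record(it, n_evals, best_f)
        denom = max(abs(prev_best), 1e-12)
        rel_impr = (prev_best - best_f) / denom
        stagnant = stagnant + 1 if rel_impr < config.rel_tol else 0
        if stagnant >= config.stagnation_window:
            log.debug("stagnation stop at iteration %d (best %.6g)", it, best_f)
            break

    return best_x, best_f, trace


def bounded_least_squares(
    residual_fn: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    bounds: Sequence[tuple[float, float]],
) -> tuple[np.ndarray, dict]:
    """Local bounded least squares (trust-region reflective).

    Returns the best iterate and a status dict; non-convergence is flagged
    (``converged`` False), never raised.
    """
    b = np.asarray(bounds, dtype=float)
    x0 = np.clip(np.asarray(x0, dtype=float), b[:, 0], b[:, 1])
    res = least_squares(residual_fn, x0, bounds=(b[:, 0], b[:, 1]), method="trf")
    return res.x, {
        "converged": bool(res.success),
        "status": int(res.status),
        "cost": float(res.cost),
        "nfev": int(res.nfev),
        "message": res.message,
    }
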