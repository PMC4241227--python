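"""Stiff-capable ODE simulation of kinetic models.

``dX/dt = S v(X, p)`` is integrated over the balanced species with LSODA
(automatic stiff/non-stiff switching).  Offline species enter the rate laws
through user-supplied input trajectories (callables of time).  A budget on
right-hand-side evaluations bounds runaway integrations of pathological
parameter candidates; exceeding it raises :class:`SimulationError`, which
the estimators convert into a sentinel objective.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import SimulationError
from .models import KineticModel

__all__ = ["SimulationResult", "simulate"]

#: concentration floor used inside the RHS so that fractional powers and
#: logarithms stay defined while the solver probes trial steps
_RHS_FLOOR = 1e-12


@dataclass
class SimulationResult:
    """Trajectories on the requested grid plus solver statistics."""

    times: np.ndarray
    trajectories: np.ndarray      # (K, m_balanced)
    species_names: list[str]
    n_rhs_evals: int
    success: bool = True


def simulate(
    model: KineticModel,
    p: Mapping[str, float] | Sequence[float],
    X0: np.ndarray | Mapping[str, float],
    times: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    max_steps: int = 5000,
    inputs: Mapping[str, Callable[[float], float]] | None = None,
) -> SimulationResult:
    """Integrate the model ODEs and sample the requested time points.

    ``p`` covers the free parameters (dict or vector); ``X0`` the balanced
    species' initial concentrations.  ``inputs`` must provide a trajectory
    for every offline species.  ``max_steps`` bounds solver work: the RHS
    may be evaluated at most ``10 * max_steps`` times.
    """
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise SimulationError("times must be strictly increasing")
    params = model.full_parameter_dict(p)
    bal = model.balanced_species
    if isinstance(X0, Mapping):
        X0v = np.array([float(X0[s]) for s in bal])
    else:
        X0v = np.asarray(X0, dtype=float)
    if X0v.shape != (len(bal),):
        raise SimulationError(f"X0 must cover the {len(bal)} balanced species")

    offline = model.offline_species
    inputs = inputs or {}
    missing = [s for s in offline if s not in inputs]
    if missing:
        raise SimulationError(f"no input trajectory for offline species {missing}")

    bal_pos = [model.species_index(s) for s in bal]
    off_pos = [model.species_index(s) for s in offline]
    max_evals = 10 * max_steps
    count = {"n": 0}
    S = model.S

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        count["n"] += 1
        if count["n"] > max_evals:
            raise _BudgetExceeded
        X = np.empty(model.n_species)
        X[bal_pos] = np.maximum(y, _RHS_FLOOR)
        for s, i in zip(offline, off_pos):
            X[i] = max(float(inputs[s](t)), _RHS_FLOOR)
        v = model.rates_matrix(X, params)
        return S @ v

    t0 = float(times[0])
    try:
        sol = solve_ivp(
            rhs, (t0, float(times[-1])), X0v, method="LSODA",
            t_eval=times, rtol=rtol, atol=atol)
    except _BudgetExceeded:
        raise SimulationError(
            f"integration exceeded the step budget ({max_evals} RHS "
            "evaluations)") from None
    if not sol.success or sol.y.shape[1] != times.size:
        raise SimulationError(f"integration failed: {sol.message}")
    traj = sol.y.T
    if not np.all(np.isfinite(traj)):
        raise SimulationError("non-finite state during integration")
    return SimulationResult(times, traj, list(bal), int(count["n"]), True)


class _BudgetExceeded(Exception):
    pass
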