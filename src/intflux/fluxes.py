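"""Integrated fluxes (IFs): cumulative quadrature, data-driven and
rate-law-driven IF tables, slope-based flux estimates, and concentration
reconstruction.

The integrated flux of reaction ``j`` at time ``t_k`` is
``eta_j(t_k) = int_0^{t_k} v_j dt`` — the per-volume extent of reaction.
From the integral form of the mass balance, ``X(t_k) - X(0) = S eta(t_k)``,
so IFs are computable directly from concentration data without smoothing
or differentiation: fully, when ``S`` has full column rank, or for the
dependent subset once the independent IFs are supplied by candidate
parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import AlignmentError, DataError
from .models import FluxPartition, KineticModel
from .timeseries import SplineFit, TimeSeriesDataset, spline_deriv, spline_eval

__all__ = [
    "IFTable",
    "cumulative_integral",
    "independent_if",
    "dependent_if_from_data",
    "full_if_from_data",
    "predicted_dependent_if",
    "reconstruct_concentrations",
    "slope_fluxes",
]


@dataclass
class IFTable:
    """Integrated-flux values per reaction per measurement time."""

    times: np.ndarray
    eta: np.ndarray               # (K, n_reactions_in_table)
    reaction_names: list[str]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.eta = np.asarray(self.eta, dtype=float)
        if self.eta.shape != (self.times.size, len(self.reaction_names)):
            raise DataError(
                f"eta shape {self.eta.shape} != "
                f"({self.times.size}, {len(self.reaction_names)})")
        if not np.all(np.isfinite(self.eta)):
            raise DataError("non-finite integrated-flux values")

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        df = pd.DataFrame(self.eta, columns=self.reaction_names)
        df.insert(0, "time", self.times)
        df.to_csv(path, index=False, float_format="%.17g")
        return path


def _quad_lagrange_integral(x: np.ndarray, a: float, b: float) -> np.ndarray:
    """Weights w such that w @ f equals the exact integral over [a, b] of
    the quadratic interpolating (x[0], f0), (x[1], f1), (x[2], f2)."""
    # work in panel-local coordinates: translation-invariant weights with
    # far less cancellation than absolute times
    shift = a
    x = np.asarray(x, dtype=float) - shift
    a, b = a - shift, b - shift
    w = np.empty(3)
    for i in range(3):
        u, v = [x[j] for j in range(3) if j != i]
        denom = (x[i] - u) * (x[i] - v)
        # integral of (t - u)(t - v) over [a, b]
        integ = ((b**3 - a**3) / 3.0
                 - (u + v) * (b**2 - a**2) / 2.0
                 + u * v * (b - a))
        w[i] = integ / denom
    return w


_WEIGHT_CACHE: dict[bytes, np.ndarray] = {}


def cumulative_weights(times: np.ndarray) -> np.ndarray:
    """Lower-triangular matrix ``W`` with ``(W @ f)[k] = int_{t_0}^{t_k} f``
    under the half-panel Simpson scheme; cached per grid."""
    t = np.asarray(times, dtype=float)
    key = t.tobytes()
    W = _WEIGHT_CACHE.get(key)
    if W is not None:
        return W
    K = t.size
    W = np.zeros((K, K))
    W[1, :3] = _quad_lagrange_integral(t[:3], t[0], t[1])
    for k in range(2, K):
        W[k] = W[k - 1]
        W[k, k - 2:k + 1] += _quad_lagrange_integral(t[k - 2:k + 1], t[k - 1], t[k])
    if len(_WEIGHT_CACHE) > 32:      # bounded cache
        _WEIGHT_CACHE.clear()
    _WEIGHT_CACHE[key] = W
    return W


def cumulative_integral(times: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Cumulative quadrature on the measurement grid, exact for quadratics.

    For each panel ``[t_{k-1}, t_k]`` (k >= 2) the increment is the exact
    integral of the quadratic through ``(t_{k-2}, t_{k-1}, t_k)``; the first
    panel ``[t_0, t_1]`` uses the quadratic through the first three points.
    This half-panel Simpson scheme needs no grid uniformity or parity and
    reproduces any polynomial of degree <= 2 exactly.

    ``values`` may be ``(K,)`` or ``(K, r)``; the result has the same shape,
    holding ``int_{t_0}^{t_k}`` in row ``k`` (row 0 is zero).
    """
    t = np.asarray(times, dtype=float)
    f = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.size < 3:
        raise DataError("cumulative_integral needs at least 3 time points")
    if np.any(np.diff(t) <= 0):
        raise DataError("times must be strictly increasing")
    squeeze = f.ndim == 1
    F = f[:, np.newaxis] if squeeze else f
    if F.shape[0] != t.size:
        raise DataError(f"values rows {F.shape[0]} != {t.size} times")
    if not np.all(np.isfinite(F)):
        raise DataError("non-finite values passed to cumulative_integral")

    out = cumulative_weights(t) @ F
    return out[:, 0] if squeeze else out


def _rates_on_data(model: KineticModel, dataset: TimeSeriesDataset,
                   reactions: Sequence[int], params: Mapping[str, float]) -> np.ndarray:
    """Rates of the given reactions at the measured concentrations, (K, r)."""
    cache = dataset.__dict__.setdefault("_X_cache", {})
    key = tuple(model.species_names)
    X = cache.get(key)
    if X is None:
        X = np.empty((dataset.K, model.n_species))
        for i, sp in enumerate(model.species_names):
            X[:, i] = dataset.column(sp)
        cache[key] = X
    return model.rates_matrix(X, params, reactions=reactions)


def independent_if(
    model: KineticModel,
    partition: FluxPartition,
    dataset: TimeSeriesDataset,
    p_I: Mapping[str, float] | Sequence[float],
) -> IFTable:
    """Independent IFs: quadrature of the independent rate laws evaluated at
    the *measured* concentrations, given candidate independent parameters."""
    params = model.fixed_parameters()
    params.update(_as_param_dict(p_I, partition.p_I))
    v = _rates_on_data(model, dataset, partition.independent_ids, params)
    eta = cumulative_integral(dataset.times, v)
    return IFTable(dataset.times, eta, list(partition.independent_names))


def predicted_dependent_if(
    model: KineticModel,
    partition: FluxPartition,
    dataset: TimeSeriesDataset,
    p_D: Mapping[str, float] | Sequence[float],
) -> IFTable:
    """Model-predicted dependent IFs: quadrature of the dependent rate laws
    at the measured concentrations, given dependent parameters."""
    params = model.fixed_parameters()
    params.update(_as_param_dict(p_D, partition.p_D))
    v = _rates_on_data(model, dataset, partition.dependent_ids, params)
    eta = cumulative_integral(dataset.times, v)
    return IFTable(dataset.times, eta, list(partition.dependent_names))


def _as_param_dict(p, names: Sequence[str]) -> dict[str, float]:
    if isinstance(p, Mapping):
        return {k: float(v) for k, v in p.items()}
    p = np.asarray(p, dtype=float)
    if p.shape != (len(names),):
        raise DataError(f"expected {len(names)} parameter values, got {p.shape}")
    return dict(zip(names, p))


def _balanced_matrix(dataset: TimeSeriesDataset, species: Sequence[str]) -> np.ndarray:
    return np.column_stack([dataset.column(s) for s in species])


def dependent_if_from_data(
    partition: FluxPartition,
    dataset: TimeSeriesDataset,
    eta_I: IFTable,
) -> IFTable:
    """Dependent IFs determined from the data and the independent IFs:

    ``eta_D(t_k) = S_D^+ (X_M(t_k) - X_M(0) - S_I eta_I(t_k))``.
    """
    if eta_I.times.shape != dataset.times.shape or not np.allclose(
            eta_I.times, dataset.times, rtol=0, atol=1e-12):
        raise AlignmentError("eta_I time grid does not match the dataset")
    X = _balanced_matrix(dataset, partition.balanced_species)
    dX = X - X[0]
    resid = dX.T - partition.S_I @ eta_I.eta.T      # (m_bal, K)
    eta_D = (partition.S_D_pinv @ resid).T
    return IFTable(dataset.times, eta_D, list(partition.dependent_names))


def full_if_from_data(S: np.ndarray, dataset: TimeSeriesDataset) -> IFTable:
    """All IFs directly from data when ``S`` has full column rank:
    ``eta(t_k) = S^+ (X_M(t_k) - X_M(0))``."""
    from .models import stoich_dof

    S = np.atleast_2d(np.asarray(S, dtype=float))
    rank, dof = stoich_dof(S)
    if dof > 0:
        raise DataError(
            f"S is column-rank deficient (rank {rank} < {S.shape[1]} reactions); "
            "use a flux partition (independent/dependent IFs) instead")
    if S.shape[0] != dataset.m:
        raise DataError("S rows do not match dataset species")
    pinv = np.linalg.inv(S) if S.shape[0] == S.shape[1] else np.linalg.pinv(S)
    dX = dataset.values - dataset.values[0]
    eta = (pinv @ dX.T).T
    return IFTable(dataset.times, eta, [f"v{j + 1}" for j in range(S.shape[1])])


def reconstruct_concentrations(
    model: KineticModel, X0: np.ndarray, eta_full: IFTable
) -> np.ndarray:
    """Predicted balanced-species concentrations from the integral form:
    ``X(t_k) = X0 + S eta(t_k)``; shape ``(K, m_balanced)``."""
    X0 = np.asarray(X0, dtype=float)
    if eta_full.eta.shape[1] != model.n_reactions:
        raise DataError(
            f"eta table covers {eta_full.eta.shape[1]} reactions, "
            f"model has {model.n_reactions}")
    if X0.shape != (len(model.balanced_species),):
        raise DataError("X0 must cover the balanced species")
    return X0[np.newaxis, :] + (model.S @ eta_full.eta.T).T


def slope_fluxes(
    partition: FluxPartition,
    spline_fits: SplineFit,
    model: KineticModel,
    p_I: Mapping[str, float] | Sequence[float],
    times: np.ndarray,
) -> np.ndarray:
    """Slope-based dependent flux estimates (incremental-estimation path):

    ``v_D(t_k) = S_D^+ (dX_M/dt|_{t_k} - S_I v_I(X(t_k), p_I))``

    with concentrations and derivatives taken from the smoothing splines.
    Returns ``(K, n_dependent)``.
    """
    times = np.asarray(times, dtype=float)
    missing = [s for s in model.species_names if s not in spline_fits.species_names]
    if missing:
        raise DataError(f"spline fits missing species {missing}")
    Xs = spline_eval(spline_fits, times)
    order = [spline_fits.species_names.index(s) for s in model.species_names]
    Xmod = Xs[:, order]
    dX = spline_deriv(spline_fits, times)
    bal_idx = [spline_fits.species_names.index(s) for s in partition.balanced_species]
    dX_bal = dX[:, bal_idx]

    params = model.fixed_parameters()
    params.update(_as_param_dict(p_I, partition.p_I))
    v_I = model.rates_matrix(Xmod, params, reactions=partition.independent_ids)
    resid = dX_bal.T - partition.S_I @ v_I.T
    return (partition.S_D_pinv @ resid).T
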