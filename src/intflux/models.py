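"""Kinetic network models: stoichiometry, rate laws and flux partitions.

A model couples a stoichiometric matrix ``S`` (rows = balanced species,
columns = reactions) with one rate law per reaction.  Two rate-law families
are supported:

* generalized mass action (GMA, power law): ``v_j = a_j * prod_i X_i**g_ji``
* simplified lin-log:                        ``v_j = a_j + sum_i g_ji * ln X_i``

Each rate-law parameter (the rate constant/offset ``a`` and the kinetic
orders / log-coefficients ``g``) is either *free* (estimated, with bounds)
or *fixed*.  Free parameters are identified by global names of the form
``a_v1`` and ``g_v1_X4`` so that every parameter belongs to exactly one
reaction — the property that lets the inner estimation run one reaction at
a time.

Species may be flagged *offline*: they appear in rate laws as externally
supplied inputs (their trajectories come from data) but have no mass
balance, hence no row in ``S``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigError, DomainError, PartitionError

__all__ = [
    "GMARateLaw",
    "LinLogRateLaw",
    "KineticModel",
    "FluxPartition",
    "eval_rates",
    "stoich_dof",
    "make_partition",
    "rank_partitions",
]

#: singular values below RANK_RTOL * s_max count as zero when ranking S.
#: Stoichiometric coefficients are small integers, so the spectral gap
#: between "structural" and "numerical-noise" singular values is wide.
RANK_RTOL = 1e-8


@dataclass
class _ParamSpec:
    """Metadata for one rate-law parameter."""

    name: str                 # global name, e.g. "a_v1" or "g_v1_X4"
    reaction: str
    role: str                 # "a" or "g"
    species: str | None       # species for "g" roles
    free: bool
    lower: float
    upper: float
    value: float | None       # fixed value, or true/default value if known


@dataclass
class GMARateLaw:
    """Power-law rate ``v = a * prod_i X_i**g_i`` over the named species.

    ``orders`` maps species name -> kinetic order.  ``free`` lists which
    roles are estimated: ``"a"`` and/or ``"g:<species>"``.  ``values``
    optionally carries known (fixed or ground-truth) numbers per role.
    """

    orders: Mapping[str, float] = field(default_factory=dict)
    free: Sequence[str] = ()
    values: Mapping[str, float] = field(default_factory=dict)
    bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    family = "gma"


@dataclass
class LinLogRateLaw:
    """Simplified lin-log rate ``v = a + sum_i g_i * ln X_i``.

    Linear in its parameters for fixed concentrations; defined only for
    positive concentrations of the named species.
    """

    coefficients: Mapping[str, float] = field(default_factory=dict)
    free: Sequence[str] = ()
    values: Mapping[str, float] = field(default_factory=dict)
    bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    family = "linlog"

    @property
    def orders(self) -> Mapping[str, float]:  # uniform access to species map
        return self.coefficients


class KineticModel:
    """A reaction network with stoichiometry, rate laws and parameter metadata.

    Parameters
    ----------
    species_names
        All species, balanced and offline, in the order used by
        concentration vectors/matrices.
    reaction_names
        Reaction identifiers, in column order of ``S``.
    S
        Stoichiometric matrix over the *balanced* species (offline species
        contribute no row), shape ``(m_balanced, n)``.
    rate_laws
        One :class:`GMARateLaw` or :class:`LinLogRateLaw` per reaction.
    offline_species
        Species treated as externally supplied inputs.
    """

    def __init__(
        self,
        species_names: Sequence[str],
        reaction_names: Sequence[str],
        S: np.ndarray,
        rate_laws: Sequence[GMARateLaw | LinLogRateLaw],
        offline_species: Iterable[str] = (),
        name: str = "model",
    ) -> None:
        self.name = name
        self.species_names = list(species_names)
        self.reaction_names = list(reaction_names)
        self.offline_species = [s for s in species_names if s in set(offline_species)]
        self.balanced_species = [s for s in self.species_names
                                 if s not in set(self.offline_species)]
        self.S = np.asarray(S, dtype=float)
        if self.S.shape != (len(self.balanced_species), len(self.reaction_names)):
            raise ConfigError(
                f"S has shape {self.S.shape}, expected "
                f"({len(self.balanced_species)}, {len(self.reaction_names)})"
            )
        if len(rate_laws) != len(self.reaction_names):
            raise ConfigError("one rate law per reaction required")
        self.rate_laws = list(rate_laws)

        self._species_idx = {s: i for i, s in enumerate(self.species_names)}
        unknown = [sp for law in self.rate_laws for sp in law.orders
                   if sp not in self._species_idx]
        if unknown:
            raise ConfigError(f"rate law references unknown species: {unknown}")

        self._build_parameter_index()

    # ------------------------------------------------------------------ #
    # parameter bookkeeping
    # ------------------------------------------------------------------ #
    def _build_parameter_index(self) -> None:
        specs: list[_ParamSpec] = []
        for rname, law in zip(self.reaction_names, self.rate_laws):
            roles = ["a"] + [f"g:{sp}" for sp in law.orders]
            free_set = set(law.free)
            stray = free_set - set(roles)
            if stray:
                raise ConfigError(f"reaction {rname}: free roles {stray} not in law")
            for role in roles:
                species = role[2:] if role.startswith("g:") else None
                gname = f"a_{rname}" if role == "a" else f"g_{rname}_{species}"
                lo, hi = law.bounds.get(role, (-np.inf, np.inf))
                specs.append(_ParamSpec(
                    name=gname, reaction=rname,
                    role="a" if role == "a" else "g",
                    species=species, free=role in free_set,
                    lower=float(lo), upper=float(hi),
                    value=law.values.get(role),
                ))
        self._param_specs = specs
        names = [s.name for s in specs]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate parameter names")  # cannot happen by construction
        self.parameter_index = {s.name: (s.reaction, s.role, s.species) for s in specs}
        self.free_parameter_names = [s.name for s in specs if s.free]
        self.bounds = {s.name: (s.lower, s.upper) for s in specs if s.free}
        for nm, (lo, hi) in self.bounds.items():
            if not (lo < hi):
                raise ConfigError(f"parameter {nm}: bounds [{lo}, {hi}] invalid")

    # ------------------------------------------------------------------ #
    @property
    def n_reactions(self) -> int:
        return len(self.reaction_names)

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    def reaction_index(self, reaction: str | int) -> int:
        if isinstance(reaction, (int, np.integer)):
            return int(reaction)
        try:
            return self.reaction_names.index(reaction)
        except ValueError:
            raise ConfigError(f"unknown reaction {reaction!r}") from None

    def species_index(self, species: str) -> int:
        return self._species_idx[species]

    def free_parameters_of(self, reactions: Iterable[str | int]) -> list[str]:
        """Free-parameter names owned by the given reactions, model order."""
        rset = {self.reaction_names[self.reaction_index(r)] for r in reactions}
        return [s.name for s in self._param_specs if s.free and s.reaction in rset]

    def true_parameters(self) -> dict[str, float] | None:
        """Ground-truth values of the free parameters, if the config carried them."""
        vals = {s.name: s.value for s in self._param_specs if s.free}
        if any(v is None for v in vals.values()):
            return None
        return {k: float(v) for k, v in vals.items()}

    def fixed_parameters(self) -> dict[str, float]:
        out = {}
        for s in self._param_specs:
            if not s.free:
                if s.value is None:
                    raise ConfigError(f"fixed parameter {s.name} has no value")
                out[s.name] = float(s.value)
        return out

    def full_parameter_dict(self, p: Mapping[str, float] | Sequence[float]) -> dict[str, float]:
        """Merge free-parameter values (dict or vector in
        ``free_parameter_names`` order) with the fixed values."""
        if not isinstance(p, Mapping):
            p = np.asarray(p, dtype=float)
            if p.shape != (len(self.free_parameter_names),):
                raise ConfigError(
                    f"parameter vector length {p.shape} != "
                    f"{len(self.free_parameter_names)} free parameters")
            p = dict(zip(self.free_parameter_names, p))
        full = self.fixed_parameters()
        full.update({k: float(v) for k, v in p.items()})
        return full

    # ------------------------------------------------------------------ #
    # rate evaluation
    # ------------------------------------------------------------------ #
    def rates_matrix(
        self,
        X: np.ndarray,
        params: Mapping[str, float],
        reactions: Sequence[str | int] | None = None,
    ) -> np.ndarray:
        """Evaluate reaction rates at one or many concentration vectors.

        ``X`` is ``(m,)`` or ``(K, m)`` over *all* species (model order);
        ``params`` must cover every parameter of the requested reactions
        (global names).  Returns ``(K, len(reactions))`` (or ``(len,)`` for
        a single vector).
        """
        Xarr = np.atleast_2d(np.asarray(X, dtype=float))
        if Xarr.shape[1] != self.n_species:
            raise ConfigError(
                f"X has {Xarr.shape[1]} columns, model has {self.n_species} species")
        if reactions is None:
            ridx = range(self.n_reactions)
        else:
            ridx = [self.reaction_index(r) for r in reactions]

        out = np.empty((Xarr.shape[0], len(list(ridx))))
        ridx = list(ridx)
        for col, j in enumerate(ridx):
            rname = self.reaction_names[j]
            law = self.rate_laws[j]
            a = params[f"a_{rname}"]
            sp = list(law.orders)
            g = np.array([params[f"g_{rname}_{s}"] for s in sp])
            if sp:
                Xs = Xarr[:, [self._species_idx[s] for s in sp]]
            else:
                Xs = np.empty((Xarr.shape[0], 0))
            if law.family == "gma":
                needs_pos = [s for s, gi in zip(sp, g)
                             if float(gi) != int(gi) or gi < 0]
                self._check_positive(Xs, sp, needs_pos, rname)
                with np.errstate(divide="ignore", invalid="ignore"):
                    out[:, col] = a * np.prod(
                        np.power(Xs, g[np.newaxis, :]), axis=1) if sp else a
            else:  # linlog
                self._check_positive(Xs, sp, sp, rname)
                out[:, col] = a + (np.log(Xs) @ g if sp else 0.0)
        if np.asarray(X).ndim == 1:
            return out[0]
        return out

    def _check_positive(self, Xs, sp, needs_pos, rname) -> None:
        for s in needs_pos:
            colv = Xs[:, sp.index(s)]
            if np.any(colv <= 0):
                raise DomainError(
                    f"non-positive concentration of species {s!r} in "
                    f"reaction {rname!r} (min={colv.min():g})")


def eval_rates(model: KineticModel, X: np.ndarray, p: Mapping[str, float] | Sequence[float]) -> np.ndarray:
    """Evaluate all reaction rates ``v(X, p)``.

    ``p`` covers the free parameters (dict by global name, or vector in
    ``model.free_parameter_names`` order); fixed values are merged in.
    """
    return model.rates_matrix(X, model.full_parameter_dict(p))


# ---------------------------------------------------------------------- #
# flux partitioning
# ---------------------------------------------------------------------- #
def stoich_dof(S: np.ndarray) -> tuple[int, int]:
    """Rank of the stoichiometric matrix and degrees of freedom ``n - rank``.

    The dof equals the dimension of the right null space of ``S``: the
    number of reactions whose integrated fluxes cannot be inferred from
    concentration changes alone.
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    sv = np.linalg.svd(S, compute_uv=False)
    tol = RANK_RTOL * (sv[0] if sv.size else 0.0)
    rank = int(np.sum(sv > tol))
    return rank, S.shape[1] - rank


@dataclass
class FluxPartition:
    """Split of the reactions into independent and dependent subsets.

    Given the integrated fluxes of the independent reactions, the dependent
    integrated fluxes are uniquely determined from concentration changes
    through the left-inverse of ``S_D``.
    """

    independent_ids: list[int]
    dependent_ids: list[int]
    independent_names: list[str]
    dependent_names: list[str]
    S_I: np.ndarray
    S_D: np.ndarray
    S_D_pinv: np.ndarray
    p_I: list[str]
    p_D: list[str]
    balanced_species: list[str]

    @property
    def n_independent(self) -> int:
        return len(self.independent_ids)

    def assemble(self, eta_I: np.ndarray, eta_D: np.ndarray) -> np.ndarray:
        """Reassemble column-blocks into original reaction order: returns a
        ``(K, n)`` array with independent columns in their original slots."""
        K = eta_I.shape[0]
        n = len(self.independent_ids) + len(self.dependent_ids)
        out = np.empty((K, n))
        out[:, self.independent_ids] = eta_I
        out[:, self.dependent_ids] = eta_D
        return out


def make_partition(model: KineticModel, independent_ids: Sequence[str | int]) -> FluxPartition:
    """Build and validate a flux partition from the chosen independent set.

    The independent set must have size ``n - rank(S)`` and leave an ``S_D``
    of full column rank (so the dependent integrated fluxes are unique).
    """
    rank, dof = stoich_dof(model.S)
    idx = [model.reaction_index(r) for r in independent_ids]
    if len(set(idx)) != len(idx):
        raise PartitionError(f"duplicate reactions in independent set {independent_ids}")
    if len(idx) != dof:
        raise PartitionError(
            f"independent set size {len(idx)} != dof {dof} (n={model.n_reactions}, "
            f"rank(S)={rank})")
    dep = [j for j in range(model.n_reactions) if j not in set(idx)]
    S_I = model.S[:, idx]
    S_D = model.S[:, dep]
    d_rank, _ = stoich_dof(S_D)
    if d_rank < S_D.shape[1]:
        raise PartitionError(
            f"S_D for independent set {[model.reaction_names[j] for j in idx]} is "
            f"column-rank deficient (rank {d_rank} < {S_D.shape[1]}): dependent "
            "integrated fluxes would not be unique")
    S_D_pinv = np.linalg.pinv(S_D)
    return FluxPartition(
        independent_ids=list(idx),
        dependent_ids=dep,
        independent_names=[model.reaction_names[j] for j in idx],
        dependent_names=[model.reaction_names[j] for j in dep],
        S_I=S_I, S_D=S_D, S_D_pinv=S_D_pinv,
        p_I=model.free_parameters_of(idx),
        p_D=model.free_parameters_of(dep),
        balanced_species=list(model.balanced_species),
    )


def rank_partitions(
    model: KineticModel,
    candidates: Sequence[Sequence[str | int]] | None = None,
    enumeration_cap: int = 12,
) -> list[FluxPartition]:
    """Enumerate/validate candidate independent sets and order them.

    Ordering follows the selection guidelines: fewest independent free
    parameters first, then smallest total width of their bound ranges,
    with a deterministic lexicographic tie-break on reaction indices.
    For ``n`` above ``enumeration_cap`` the caller must supply candidates.
    """
    _, dof = stoich_dof(model.S)
    if candidates is None:
        if model.n_reactions > enumeration_cap:
            raise PartitionError(
                f"n={model.n_reactions} exceeds the exhaustive-enumeration cap "
                f"({enumeration_cap}); supply candidate independent sets")
        candidates = list(itertools.combinations(range(model.n_reactions), dof))
    if not candidates:
        raise PartitionError("no candidate partitions supplied")

    valid: list[tuple[tuple, FluxPartition]] = []
    for cand in candidates:
        try:
            part = make_partition(model, list(cand))
        except PartitionError:
            continue
        widths = sum(
            (model.bounds[nm][1] - model.bounds[nm][0]) for nm in part.p_I
        ) if part.p_I else 0.0
        key = (len(part.p_I), widths, tuple(part.independent_ids))
        valid.append((key, part))
    if not valid:
        raise PartitionError("no valid partition among the candidates")
    valid.sort(key=lambda kv: kv[0])
    return [p for _, p in valid]
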