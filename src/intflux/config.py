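"""Declarative model configuration (YAML).

Schema::

    name: branched
    species: [X1, X2, X3, X4]
    offline: []                     # species supplied as inputs, not balanced
    initial_conditions: {X1: 0.5, ...}
    reactions:
      - name: v1
        law: gma                    # or linlog
        stoichiometry: {X1: 1}      # balanced species only; omitted = 0
        a: {free: true, lower: 0, upper: 25, true: 12.0}
        g:
          X4: {free: true, lower: -2, upper: 0, true: -0.8}

Per-parameter entries accept ``free`` (default true), ``lower``/``upper``
bounds, ``true`` (ground-truth value, used by synthetic benchmarks and
recovery scoring) and ``value`` (required when ``free: false``).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .errors import ConfigError
from .models import GMARateLaw, KineticModel, LinLogRateLaw

__all__ = ["load_model_config", "model_from_dict", "default_config_path"]

_CONFIG_DIR = Path(__file__).parent / "configs"


def default_config_path(name: str) -> Path:
    """Path of a packaged fixture config, e.g. ``branched_synthetic``."""
    p = _CONFIG_DIR / f"{name}.yaml"
    if not p.exists():
        raise ConfigError(
            f"no packaged config {name!r}; available: "
            f"{sorted(q.stem for q in _CONFIG_DIR.glob('*.yaml'))}")
    return p


def load_model_config(path: str | Path) -> tuple[KineticModel, dict[str, float] | None, dict[str, float]]:
    """Load a model config file.

    Returns ``(model, p_true, X0)`` where ``p_true`` is the free-parameter
    truth dict (None if the config omits any truth value) and ``X0`` maps
    balanced species to initial concentrations.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        return model_from_dict(raw)
    except ConfigError as e:
        raise ConfigError(f"{path}: {e}") from None


def _param_entry(entry, what: str) -> dict:
    if isinstance(entry, (int, float)):
        return {"free": False, "value": float(entry)}
    if not isinstance(entry, Mapping):
        raise ConfigError(f"{what}: expected a number or mapping")
    # YAML parses a bare `true:` key as boolean True; normalize it back
    return {("true" if k is True else k): v for k, v in entry.items()}


def model_from_dict(raw: Mapping) -> tuple[KineticModel, dict[str, float] | None, dict[str, float]]:
    for key in ("species", "reactions"):
        if key not in raw:
            raise ConfigError(f"missing required key {key!r}")
    species = list(raw["species"])
    offline = list(raw.get("offline", []))
    unknown_off = [s for s in offline if s not in species]
    if unknown_off:
        raise ConfigError(f"offline species not in species list: {unknown_off}")
    balanced = [s for s in species if s not in set(offline)]

    reaction_names, laws = [], []
    S_cols = []
    for rec in raw["reactions"]:
        rname = rec.get("name") or f"v{len(reaction_names) + 1}"
        reaction_names.append(rname)
        stoich = rec.get("stoichiometry", {}) or {}
        bad = [s for s in stoich if s not in species]
        if bad:
            raise ConfigError(f"reaction {rname}: unknown species {bad} in stoichiometry")
        off_bad = [s for s in stoich if s in set(offline)]
        if off_bad:
            raise ConfigError(
                f"reaction {rname}: offline species {off_bad} cannot appear in "
                "the stoichiometry (no balance row)")
        S_cols.append([float(stoich.get(s, 0.0)) for s in balanced])

        family = str(rec.get("law", "gma")).lower()
        if family not in ("gma", "linlog"):
            raise ConfigError(f"reaction {rname}: unknown rate-law family {family!r}")
        a_entry = _param_entry(rec.get("a", {}), f"reaction {rname}: a")
        g_entries = {sp: _param_entry(e, f"reaction {rname}: g[{sp}]")
                     for sp, e in (rec.get("g", {}) or {}).items()}

        free, values, bounds = [], {}, {}

        def handle(role: str, entry: dict) -> None:
            is_free = bool(entry.get("free", True))
            if is_free:
                free.append(role)
                lo, hi = entry.get("lower"), entry.get("upper")
                if lo is None or hi is None:
                    raise ConfigError(
                        f"reaction {rname}: free parameter {role} needs "
                        "lower and upper bounds")
                bounds[role] = (float(lo), float(hi))
                if "true" in entry:
                    values[role] = float(entry["true"])
            else:
                if "value" not in entry and "true" not in entry:
                    raise ConfigError(
                        f"reaction {rname}: fixed parameter {role} needs a value")
                values[role] = float(entry.get("value", entry.get("true")))

        handle("a", a_entry)
        for sp, entry in g_entries.items():
            handle(f"g:{sp}", entry)

        orders = {sp: values.get(f"g:{sp}", 0.0) for sp in g_entries}
        if family == "gma":
            laws.append(GMARateLaw(orders=orders, free=free, values=values,
                                   bounds=bounds))
        else:
            laws.append(LinLogRateLaw(coefficients=orders, free=free,
                                      values=values, bounds=bounds))

    S = np.array(S_cols, dtype=float).T if S_cols else np.zeros((len(balanced), 0))
    model = KineticModel(species, reaction_names, S, laws,
                         offline_species=offline,
                         name=str(raw.get("name", "model")))
    X0_raw = raw.get("initial_conditions", {}) or {}
    X0 = {s: float(X0_raw[s]) for s in balanced if s in X0_raw}
    return model, model.true_parameters(), X0
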