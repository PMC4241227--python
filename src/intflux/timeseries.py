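"""Time-series concentration data: parsing, noise injection, smoothing.

Tables are delimited text with a leading time column and one column per
species.  Technical replicates are separate files sharing a basename with
a ``_rep<k>`` suffix.  Smoothing uses least-squares piecewise polynomials
(B-splines with interior knots of multiplicity ``o - 1``, giving continuity
of value and first derivative at the ``s - 1`` equally spaced breakpoints).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline, make_lsq_spline

from .errors import DataError

__all__ = [
    "TimeSeriesDataset",
    "read_timeseries",
    "write_timeseries",
    "add_noise",
    "interpolate_missing",
    "SplineFit",
    "fit_spline",
    "spline_eval",
    "spline_deriv",
]

log = logging.getLogger(__name__)


@dataclass
class TimeSeriesDataset:
    """Measured concentrations on a common time grid.

    ``values`` is ``(K, m)``; ``mask`` is True where a value was observed
    (False marks missing cells, which hold NaN until interpolated).
    """

    times: np.ndarray
    values: np.ndarray
    species_names: list[str]
    replicate_id: str | None = None
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1:
            raise DataError("times must be one-dimensional")
        if self.values.shape != (self.times.size, len(self.species_names)):
            raise DataError(
                f"values shape {self.values.shape} != "
                f"({self.times.size}, {len(self.species_names)})")
        d = np.diff(self.times)
        if np.any(d <= 0):
            k = int(np.argmax(d <= 0))
            raise DataError(
                f"times must be strictly increasing (violated between rows "
                f"{k} and {k + 1}: {self.times[k]} -> {self.times[k + 1]})")
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise DataError("mask shape mismatch")

    @property
    def K(self) -> int:
        return self.times.size

    @property
    def m(self) -> int:
        return len(self.species_names)

    @property
    def complete(self) -> bool:
        return bool(self.mask.all())

    def column(self, species: str) -> np.ndarray:
        try:
            return self.values[:, self.species_names.index(species)]
        except ValueError:
            raise DataError(f"species {species!r} not in dataset") from None

    def subset(self, species: Sequence[str]) -> "TimeSeriesDataset":
        idx = [self.species_names.index(s) for s in species]
        return TimeSeriesDataset(
            self.times.copy(), self.values[:, idx].copy(), list(species),
            replicate_id=self.replicate_id, mask=self.mask[:, idx].copy())


def read_timeseries(
    path: str | Path,
    schema: Sequence[str] | None = None,
    time_column: str | None = None,
) -> TimeSeriesDataset:
    """Parse a delimited (CSV/TSV) time-series table.

    The first column (or ``time_column``) holds measurement times; the
    remaining columns hold species concentrations.  Blank cells are flagged
    missing, never silently filled.  If ``schema`` (expected species names)
    is given, unknown columns are a parse error.
    """
    path = Path(path)
    import csv

    with open(path, newline="") as fh:
        head = fh.read(4096)
    try:
        sep = csv.Sniffer().sniff(head, delimiters=",;\t ").delimiter
    except csv.Error:
        sep = ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if df.shape[1] < 2:
        raise DataError(f"{path}: need a time column and at least one species column")
    tcol = time_column or df.columns[0]
    if tcol not in df.columns:
        raise DataError(f"{path}: no time column {tcol!r}")
    species = [c for c in df.columns if c != tcol]
    if schema is not None:
        unknown = [c for c in species if c not in set(schema)]
        if unknown:
            raise DataError(f"{path}: unknown species column(s) {unknown}")
    times = df[tcol].to_numpy(dtype=float)
    if np.any(pd.isna(times)):
        raise DataError(f"{path}: missing value in time column")
    if np.any(np.diff(times) == 0):
        raise DataError(f"{path}: duplicate time points")
    values = df[species].to_numpy(dtype=float)
    ds = TimeSeriesDataset(times, values, species,
                           replicate_id=_replicate_id_from_name(path))
    log.info("read %s: %d rows, %d species, %d missing cells",
             path, ds.K, ds.m, int((~ds.mask).sum()))
    return ds


def _replicate_id_from_name(path: Path) -> str | None:
    stem = path.stem
    if "_rep" in stem:
        return stem.rsplit("_rep", 1)[-1] and "rep" + stem.rsplit("_rep", 1)[-1]
    return None


def write_timeseries(dataset: TimeSeriesDataset, path: str | Path,
                     time_name: str = "time") -> Path:
    """Write a dataset as CSV with full float precision (round-trip safe)."""
    path = Path(path)
    df = pd.DataFrame(dataset.values, columns=dataset.species_names)
    df.insert(0, time_name, dataset.times)
    df.to_csv(path, index=False, float_format="%.17g")
    log.info("wrote %s: %d rows", path, dataset.K)
    return path


def add_noise(
    dataset: TimeSeriesDataset,
    cv: float,
    n_replicates: int,
    seed: int | None = None,
    floor_frac: float = 1e-6,
) -> list[TimeSeriesDataset]:
    """Generate technical replicates with additive Gaussian noise.

    Each cell receives independent noise ``Normal(0, (cv * X)^2)`` —
    zero-mean with coefficient of variation ``cv``.  Values falling below
    ``floor_frac * max(X)`` are clipped to that floor, because power-law and
    lin-log rate laws require positive concentrations.
    """
    if cv < 0:
        raise ValueError(f"cv must be non-negative, got {cv}")
    rng = np.random.default_rng(seed)
    floor = floor_frac * float(np.nanmax(dataset.values))
    out = []
    for r in range(n_replicates):
        noisy = dataset.values + rng.normal(0.0, 1.0, dataset.values.shape) * (
            cv * dataset.values)
        n_clip = int(np.sum(noisy < floor))
        if n_clip:
            log.info("replicate %d: clipped %d cells to floor %g", r + 1, n_clip, floor)
        noisy = np.maximum(noisy, floor)
        out.append(TimeSeriesDataset(
            dataset.times.copy(), noisy, list(dataset.species_names),
            replicate_id=f"rep{r + 1}", mask=dataset.mask.copy()))
    return out


def interpolate_missing(dataset: TimeSeriesDataset) -> TimeSeriesDataset:
    """Fill missing cells by linear interpolation in time.

    Interior gaps are linearly interpolated from the nearest observed
    neighbours; gaps at the boundaries take the nearest observed value.
    """
    if dataset.complete:
        return dataset
    values = dataset.values.copy()
    for j, sp in enumerate(dataset.species_names):
        obs = dataset.mask[:, j]
        if obs.sum() < 2:
            raise DataError(
                f"species {sp!r} has {int(obs.sum())} observed point(s); "
                "need at least 2 to interpolate")
        values[~obs, j] = np.interp(
            dataset.times[~obs], dataset.times[obs], dataset.values[obs, j])
    return replace(dataset, values=values,
                   mask=np.ones_like(dataset.mask, dtype=bool))


@dataclass
class SplineFit:
    """Least-squares piecewise-polynomial fit of every species column."""

    splines: list[BSpline]
    species_names: list[str]
    sections: int
    degree: int
    t_min: float
    t_max: float

    @property
    def breakpoints(self) -> np.ndarray:
        return np.linspace(self.t_min, self.t_max, self.sections + 1)


def fit_spline(dataset: TimeSeriesDataset, s: int, o: int) -> SplineFit:
    """Fit degree-``o`` least-squares piecewise polynomials with ``s``
    equal-width sections per species.

    Interior breakpoints carry knot multiplicity ``o - 1``, enforcing
    continuity of value and first derivative.  Missing values must be
    interpolated first (see :func:`interpolate_missing`).
    """
    if s < 1 or o < 1:
        raise ValueError(f"need s >= 1 and o >= 1, got (s, o) = ({s}, {o})")
    if not dataset.complete:
        raise DataError("dataset has missing values; run interpolate_missing first")
    n_coef = (o + 1) + (s - 1) * (o - 1)
    if dataset.K < s * (o + 1):
        warnings.warn(
            f"only K={dataset.K} points for (s, o)=({s}, {o}); "
            f"recommended K >= {s * (o + 1)}", stacklevel=2)
    if dataset.K < n_coef:
        raise DataError(
            f"K={dataset.K} points cannot determine {n_coef} spline coefficients")
    t0, t1 = float(dataset.times[0]), float(dataset.times[-1])
    interior = np.linspace(t0, t1, s + 1)[1:-1]
    knots = np.concatenate([
        np.full(o + 1, t0), np.repeat(interior, max(o - 1, 0)), np.full(o + 1, t1)])
    fits = [make_lsq_spline(dataset.times, dataset.values[:, j], knots, k=o)
            for j in range(dataset.m)]
    return SplineFit(fits, list(dataset.species_names), s, o, t0, t1)


def _check_interval(fit: SplineFit, t: np.ndarray) -> None:
    eps = 1e-12 * max(1.0, abs(fit.t_max))
    if np.any(t < fit.t_min - eps) or np.any(t > fit.t_max + eps):
        raise DataError(
            f"evaluation time outside fitted interval [{fit.t_min}, {fit.t_max}]")


def spline_eval(fit: SplineFit, t: float | np.ndarray) -> np.ndarray:
    """Evaluate the fitted smoothing curves; shape ``(K, m)`` (or ``(m,)``)."""
    tarr = np.atleast_1d(np.asarray(t, dtype=float))
    _check_interval(fit, tarr)
    out = np.column_stack([spl(tarr) for spl in fit.splines])
    return out[0] if np.isscalar(t) or np.asarray(t).ndim == 0 else out


def spline_deriv(fit: SplineFit, t: float | np.ndarray) -> np.ndarray:
    """Evaluate first derivatives of the smoothing curves (dX_M/dt estimates)."""
    tarr = np.atleast_1d(np.asarray(t, dtype=float))
    _check_interval(fit, tarr)
    out = np.column_stack([spl.derivative()(tarr) for spl in fit.splines])
    return out[0] if np.isscalar(t) or np.asarray(t).ndim == 0 else out
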