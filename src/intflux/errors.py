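"""Exception hierarchy for intflux."""


class IntfluxError(Exception):
    """Base class for all intflux errors."""


class ConfigError(IntfluxError):
    """Malformed model/run configuration."""


class DomainError(IntfluxError):
    """Rate-law evaluation outside its mathematical domain (e.g. log of a
    non-positive concentration), naming the species and reaction involved."""


class PartitionError(IntfluxError):
    """Invalid independent/dependent flux partition (wrong size or
    rank-deficient dependent stoichiometric submatrix)."""


class DataError(IntfluxError):
    """Malformed or inconsistent time-series data."""


class AlignmentError(IntfluxError):
    """Time grids of two objects that must share a grid do not match."""


class SimulationError(IntfluxError):
    """ODE integration failed (step-budget exceeded or non-finite state)."""


class EstimationError(IntfluxError):
    """Estimation could not be set up or completed."""
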