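"""Exception hierarchy."""


class KipukaError(Exception):
    """Base class for all package errors."""


class ParseError(KipukaError):
    """Malformed input that could not be parsed."""


class ValidationError(KipukaError):
    """Input parsed but violates a structural invariant."""


class DataError(KipukaError):
    """Missing or inconsistent data values (e.g. a species without a trait)."""


class SimulationError(KipukaError):
    """A stochastic simulation failed to satisfy its stopping condition."""


class FitError(KipukaError):
    """Numerical model fitting failed to converge."""


class ContractError(KipukaError):
    """Mismatch between components that must agree (e.g. statistic registries)."""
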