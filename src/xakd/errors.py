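"""Exception taxonomy shared across the package."""


class XakdError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(XakdError, ValueError):
    """A dataset or model specification violates its invariants."""


class ProbeError(XakdError, ValueError):
    """A representation-capture request cannot be satisfied."""


class PartitionError(XakdError, ValueError):
    """A stage partition cannot be formed (e.g. fewer layers than stages)."""


class ValidationError(XakdError, ValueError):
    """Inputs to a similarity/statistics routine are malformed."""


class DegenerateDataError(XakdError, ValueError):
    """Constant/zero-variance inputs make the requested statistic undefined."""


class NumericalError(XakdError, ArithmeticError):
    """An eigensolve or other numerical routine failed or went non-finite."""


class MatchingError(XakdError, RuntimeError):
    """Layer matching could not produce a bridge pair."""


class ConfigError(XakdError, ValueError):
    """A run configuration is inconsistent with the models or data."""
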