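"""Exception hierarchy shared across the toolkit."""


class ConsensusKitError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(ConsensusKitError, ValueError):
    """Input data violates a structural or range constraint."""


class ConvergenceError(ConsensusKitError, RuntimeError):
    """An iterative solver failed to reach its tolerance."""


class DegenerateDataError(ConsensusKitError, ValueError):
    """The requested statistic is undefined for this data (e.g. zero variance)."""
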