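"""Exception hierarchy shared across the package."""


class MRError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MRError):
    """Bad user configuration: missing column mappings, invalid CLI options."""


class ValidationError(MRError):
    """Input data violates an invariant (non-positive SE, duplicate rsID, ...)."""


class InsufficientInstrumentsError(MRError):
    """An estimator was asked to run with fewer instruments than it needs."""


class DegenerateInstrumentError(MRError):
    """An instrument with a zero exposure effect cannot form a Wald ratio."""


class NoOverlapError(MRError):
    """Exposure and outcome tables share no SNPs."""
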