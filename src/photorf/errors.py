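"""Exception hierarchy shared across the package."""


class PhotorfError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PhotorfError):
    """A file does not conform to the documented interchange format."""


class DataError(PhotorfError):
    """A file parses but its contents violate a data contract
    (non-monotone time axis, non-uniform sampling, broken invariant)."""


class InputError(PhotorfError):
    """Caller-supplied arguments violate a precondition."""


class DomainError(PhotorfError):
    """A value lies outside the supported domain of a model."""


class DegenerateFitError(PhotorfError):
    """The data cannot identify the model parameters (flat series etc.)."""


class NotEstimableError(PhotorfError):
    """The requested quantity cannot be estimated from the given inputs."""
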