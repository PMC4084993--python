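"""Exception types shared across the package."""


class DecophyloError(Exception):
    """Base class for all package errors."""


class FormatError(DecophyloError, ValueError):
    """A file could not be parsed in the expected format."""


class ValidationError(DecophyloError, ValueError):
    """Parsed input violates a structural invariant (e.g. non-ultrametric tree)."""


class ParameterError(DecophyloError, ValueError):
    """A numeric or structural parameter is out of its admissible range."""


class DataError(DecophyloError, ValueError):
    """Observed data are inconsistent with the model state space."""
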