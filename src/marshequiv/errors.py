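"""Exception hierarchy for marshequiv."""


class MarshEquivError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MarshEquivError):
    """A study design, effect spec, or pipeline config is invalid."""


class ValidationError(MarshEquivError):
    """An input table violates its documented schema.

    ``errors`` holds one message per violation, each naming the
    offending column/row so the caller can fix the file.
    """

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


class DegenerateSDError(MarshEquivError):
    """A pooled standard deviation is zero, so the Z-score is undefined."""


class IncompleteProfileError(MarshEquivError):
    """A soil core does not span the full 0-20 cm profile."""
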