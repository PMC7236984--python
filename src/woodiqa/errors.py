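"""Exception hierarchy shared across the pipeline stages."""


class WoodIQAError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(WoodIQAError, ValueError):
    """Malformed or out-of-range input data (e.g. a rating outside 1..5)."""


class DegenerateInputError(WoodIQAError, ValueError):
    """A sample collection too small or too degenerate to fit a distribution."""


class JoinError(WoodIQAError, ValueError):
    """Tables that must join on image id contain unmatched ids."""

    def __init__(self, message: str, unmatched=()):
        super().__init__(message)
        self.unmatched = tuple(unmatched)
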