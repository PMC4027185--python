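"""Exception types shared across the package."""


class SpliceScreenError(Exception):
    """Base class for all package-specific errors."""


class AmbiguousBaseError(SpliceScreenError):
    """A window handed to a strict scorer contains a non-ACGT character."""


class FlankTooShortError(SpliceScreenError):
    """A flank is too short for the requested splice-site window.

    Carries the number of missing nucleotides in ``deficit``.
    """

    def __init__(self, message: str, deficit: int = 0):
        super().__init__(message)
        self.deficit = deficit
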