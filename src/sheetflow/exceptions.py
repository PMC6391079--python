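"""Exception types shared across the package."""


class SheetflowError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(SheetflowError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(SheetflowError, ValueError):
    """Input is structurally valid but the quantity is undefined on it
    (e.g. zero-variance velocity series, identically-zero MSD)."""


class FormatError(SheetflowError, IOError):
    """A file or container does not match the expected on-disk layout."""
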