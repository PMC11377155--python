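"""Exception types shared across the package."""


class ValidationError(ValueError):
    """A configuration or input value violates a documented invariant."""


class PlacementError(RuntimeError):
    """The simulated field is too small to place the requested cells without overlap."""


class FormatError(IOError):
    """A file on disk does not match the expected stack / table schema."""


class ModeError(ValueError):
    """An operation was invoked under a detector mode that does not define it."""
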