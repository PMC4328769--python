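"""Exception types shared across the package."""


class RadscapeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RadscapeError):
    """A scenario, design, or parameter set violates its invariants."""


class FormatError(RadscapeError):
    """Malformed input file (ragged alignment, bad catalog row, ...)."""


class EmptyInputError(RadscapeError):
    """An input that must be non-empty is empty."""


class DegenerateInputError(RadscapeError):
    """The computation is undefined for this input (e.g. a star reference
    tree in topology saturation, or zero comparable sites in a distance)."""
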