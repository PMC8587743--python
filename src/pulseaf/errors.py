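"""Exception hierarchy shared across the package."""


class PulseAFError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PulseAFError):
    """A file did not conform to the expected on-disk format."""


class ParameterError(PulseAFError, ValueError):
    """A configuration value is outside its valid range."""


class InsufficientDataError(PulseAFError, ValueError):
    """Too few beats/intervals/samples to compute the requested quantity."""


class StratificationError(PulseAFError, ValueError):
    """A stratified split or fold cannot be formed (e.g. single-class input)."""


class EmptyDatasetError(PulseAFError, ValueError):
    """Every candidate segment was dropped; nothing left to process."""
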