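"""Exception hierarchy."""


class StainmapError(Exception):
    """Base class for all package errors."""


class InputError(StainmapError):
    """An input file is missing, unreadable, or has an unsupported format."""


class ConfigurationError(StainmapError):
    """A configuration value is invalid or incomplete."""


class ContractError(StainmapError):
    """Two objects passed together violate a mutual precondition."""


class DetectionError(StainmapError):
    """Confinement geometry could not be detected from the data."""
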