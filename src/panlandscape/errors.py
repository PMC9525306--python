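"""Exception hierarchy shared across the package."""


class PanlandscapeError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(PanlandscapeError):
    """A configuration value is invalid or inconsistent."""


class SizingError(ConfigError):
    """A simulated object does not fit in the space requested for it."""


class CoordinateError(PanlandscapeError):
    """A genomic coordinate falls outside its chromosome or interval."""


class DataIntegrityError(PanlandscapeError):
    """Input records contradict each other (e.g. one bubble, two pan locations)."""
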