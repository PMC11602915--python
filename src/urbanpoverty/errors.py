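"""Exception hierarchy."""


class UrbanPovertyError(Exception):
    """Base class for all package errors."""


class ConfigurationError(UrbanPovertyError):
    """An invalid configuration value; the message names the offending field."""


class MappingError(UrbanPovertyError):
    """A column mapping does not cover a mandatory variable."""


class RecodeError(UrbanPovertyError):
    """A source value could not be recoded to a canonical category."""


class EmptyDomainError(UrbanPovertyError):
    """An estimate was requested over an empty subset of households."""


class DegenerateDataError(UrbanPovertyError):
    """Zero variance or all-missing input where variation is required."""
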