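"""Exception hierarchy shared across the pipeline stages."""


class CrisisPulseError(Exception):
    """Base class for all package errors."""


class InputError(CrisisPulseError):
    """A required input file is missing or unreadable."""


class FormatError(CrisisPulseError):
    """A file exists but violates the expected dialect."""


class ConfigurationError(CrisisPulseError):
    """A configuration value is missing, inconsistent, or refers to
    something that does not exist (unknown country, wrong-language lexicon)."""


class EmptyPhaseError(CrisisPulseError):
    """A country/phase selection matched no tweets."""


class MissingPeriodError(CrisisPulseError):
    """A full sentiment table was requested but one period has no data."""
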