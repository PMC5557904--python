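"""Exception hierarchy shared across the package."""


class SomaseError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SomaseError):
    """A file does not conform to its declared dialect."""


class DuplicateRecordError(FormatError):
    """The same (sample, site) key occurs more than once in one input."""


class ConfigError(SomaseError):
    """A configuration value is missing, malformed, or infeasible."""


class UndefinedVafError(SomaseError):
    """VAF requested at a site with zero sequencing depth."""


class InsufficientDataError(SomaseError):
    """Too few observations to run the requested statistic."""


class JoinError(SomaseError):
    """Two keyed tables that must match have orphan keys."""
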