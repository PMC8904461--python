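"""Exception hierarchy shared by all ssrid modules."""


class SsridError(Exception):
    """Base class for all package errors."""


class FormatError(SsridError):
    """A genotype file does not follow the declared text format."""


class ValidationError(SsridError):
    """A data structure violates one of its invariants."""


class UndefinedStatisticError(SsridError):
    """A statistic is undefined for the given data (e.g. zero typed individuals)."""


class ConfigError(SsridError):
    """A simulation or pipeline configuration is invalid."""
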