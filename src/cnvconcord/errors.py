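"""Exception hierarchy for cnvconcord."""


class CnvConcordError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CnvConcordError):
    """A configuration problem: missing column, unknown keyword, bad bins."""


class ValidationError(CnvConcordError):
    """Input data violates a documented contract."""


class ParseError(CnvConcordError):
    """A row of an input table could not be parsed."""


class SimulationError(CnvConcordError):
    """The simulator could not satisfy its configuration."""


class UndefinedStatisticError(CnvConcordError):
    """A statistic is undefined for the given input (e.g. d with zero calls)."""
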