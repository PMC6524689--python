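"""Exception hierarchy for stopsig."""


class StopsigError(Exception):
    """Base class for all stopsig errors."""


class ConfigError(StopsigError):
    """Invalid task design, cohort specification, or pipeline configuration."""


class ParseError(StopsigError):
    """Malformed trial-level or summary-level input data.

    Where possible the message names the offending row.
    """


class EstimationError(StopsigError):
    """A session does not support the requested estimate (e.g. no stop trials)."""


class NumericalError(StopsigError):
    """A quadrature or root-finding step failed to converge; carries diagnostics."""
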