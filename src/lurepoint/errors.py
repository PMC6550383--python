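"""Exceptions and warnings shared across the package."""


class LurepointError(Exception):
    """Base class for package errors."""


class SchemaError(LurepointError):
    """An input table is missing a required column or has a bad vocabulary value."""


class ParseError(LurepointError):
    """A cell could not be coerced to its expected type; message names the row."""


class ConvergenceError(LurepointError):
    """A model fit failed (e.g. complete separation in a logistic fit)."""


class DesignError(LurepointError):
    """A sampling design is infeasible (MU smaller than one quadrat, pi > 1, ...)."""


class StopRuleViolationWarning(UserWarning):
    """A survey table records activity in a quadrat after its first detection."""
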