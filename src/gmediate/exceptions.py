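"""Exception hierarchy for gmediate.

All package errors derive from :class:`GmediateError` so callers can catch
pipeline failures without masking programming errors.
"""


class GmediateError(Exception):
    """Base class for all gmediate errors."""


class StructuralSpecificationError(GmediateError):
    """A data-generating process is mis-specified (e.g. non-topological parent order)."""


class ParameterError(GmediateError):
    """An operation was called with an out-of-range parameter."""


class DataError(GmediateError):
    """The supplied data cannot support the requested computation."""


class UndefinedOddsError(GmediateError):
    """A counterfactual scenario produced a prevalence of 0 or 1, so odds are undefined."""


class UnsupportedConfigurationError(GmediateError):
    """Exact enumeration was requested for a system it cannot handle (e.g. numeric variables)."""


class CannotImputeError(GmediateError):
    """A column cannot be imputed (e.g. it is 100% missing)."""


class ConfigError(GmediateError):
    """A study configuration is invalid."""
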