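"""Exception hierarchy shared across the package."""


class CoresistError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CoresistError, ValueError):
    """Invalid configuration (bad parameter values, dangling references)."""


class InsufficientDataError(CoresistError, ValueError):
    """Too few observations to carry out the requested computation."""


class DegenerateDataError(CoresistError, ValueError):
    """Input with no variation where variation is required (e.g. all values equal)."""


class DrugLookupError(CoresistError, KeyError):
    """A drug identifier is not present in the object being queried."""


class GeneLookupError(CoresistError, KeyError):
    """A gene identifier is not present in the expression matrix."""


class EmptyPanelError(CoresistError, ValueError):
    """A resistant-line panel is empty, so conditional frequencies are undefined."""


class EmptyProfileError(CoresistError, ValueError):
    """No overlapping cell lines between a co-resistance case and a feature table."""


class FitError(CoresistError, RuntimeError):
    """Nonlinear fit failed to converge from every starting point."""


class SchemaError(CoresistError, ValueError):
    """A file does not conform to the expected tabular schema."""
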