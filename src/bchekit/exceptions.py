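"""Exception hierarchy shared across the package."""


class BcheKitError(Exception):
    """Base class for all package-specific errors."""


class InputError(BcheKitError, ValueError):
    """Invalid data passed to an operation (negative concentration, short window, ...)."""


class ConfigurationError(BcheKitError, ValueError):
    """Inconsistent model/parameter configuration (enabled branch without its constant, ...)."""


class NumericError(BcheKitError, RuntimeError):
    """Integrator or optimizer failure; carries diagnostics in the message."""


class ParseError(BcheKitError, ValueError):
    """Malformed input file; names the offending column or row."""
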