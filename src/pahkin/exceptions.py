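"""Exception hierarchy for pahkin."""


class PahkinError(Exception):
    """Base class for all package errors."""


class ValidationError(PahkinError, ValueError):
    """Invalid parameter values, design settings, or input data."""


class ParseError(PahkinError, ValueError):
    """Malformed input file; carries line numbers where possible."""


class FittingError(PahkinError, RuntimeError):
    """Fitting could not proceed or did not converge; message carries diagnostics."""


class IntegrationError(PahkinError, RuntimeError):
    """Numerical ODE integration failed; message carries solver diagnostics."""
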