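"""Exception hierarchy.

Validation errors map to CLI exit code 2, numerical failures to 3.
"""


class CortexForgeError(Exception):
    """Base class for all package errors."""


class ValidationError(CortexForgeError, ValueError):
    """Invalid parameters, configuration or input data."""


class IntegrationError(CortexForgeError, RuntimeError):
    """The ODE integrator produced a non-finite state or failed to converge."""


class FitError(CortexForgeError, RuntimeError):
    """A least-squares or root-finding procedure did not converge."""


class SegmentationError(CortexForgeError, RuntimeError):
    """No objects could be segmented from an image stack."""


class InsufficientDataError(CortexForgeError, ValueError):
    """Too few usable samples for the requested operation."""
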