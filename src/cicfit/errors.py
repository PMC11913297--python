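"""Exception hierarchy for cicfit.

All package-specific failures derive from :class:`CicFitError` so callers can
catch one base class. The distinctions matter operationally: a
``DegenerateSupportError`` means the proposal missed the support of the target
(a sampling problem), while a ``FitFailedError`` means optimization collapsed
for a particular model dimension (a fitting problem the driver can route
around by skipping that dimension).
"""


class CicFitError(Exception):
    """Base class for all cicfit errors."""


class InvalidArgumentError(CicFitError, ValueError):
    """An argument violates a documented precondition."""


class InvalidTargetError(CicFitError, ValueError):
    """Target evaluations are negative or non-finite."""


class DegenerateSupportError(CicFitError, RuntimeError):
    """All importance weights are zero: the proposal misses the target support."""


class InsufficientSupportError(CicFitError, RuntimeError):
    """Fewer positively weighted points than mixture components requested."""


class FitFailedError(CicFitError, RuntimeError):
    """Every attempt to fit a model (or every candidate dimension) failed."""


class OracleFailureError(CicFitError, RuntimeError):
    """A brute-force oracle (quadrature/Monte Carlo) did not converge."""


class ConfigError(CicFitError, ValueError):
    """A run configuration file violates the schema."""
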