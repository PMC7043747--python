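"""Exception hierarchy.

Everything derives from :class:`CredSurvError` so callers can catch the
package's failures with a single ``except`` clause; the subclasses mirror the
distinct failure modes of the pipeline (bad input data, bad configuration,
degenerate designs, sampler breakdown, evaluation outside the fitted range).
"""


class CredSurvError(Exception):
    """Base class for all credsurv errors."""


class ValidationError(CredSurvError, ValueError):
    """Input data violates an invariant (negative time, non-binary flag, NaN...)."""


class ConfigurationError(CredSurvError, ValueError):
    """A user-supplied configuration value is inconsistent or out of range."""


class DegenerateDesignError(CredSurvError, ValueError):
    """A design column is constant (or otherwise carries no information)."""


class SamplerError(CredSurvError, RuntimeError):
    """The MCMC sampler encountered an unrecoverable numerical failure."""


class StratificationError(CredSurvError, ValueError):
    """Arm-stratified fitting is impossible (e.g. an arm with no events)."""


class ExtrapolationError(CredSurvError, ValueError):
    """A survival quantity was requested beyond the fitted time partition."""
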