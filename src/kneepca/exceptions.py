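"""Exception types raised across the package."""


class KneePCAError(Exception):
    """Base class for all package-specific errors."""


class GimbalLockError(KneePCAError):
    """Cardan decomposition is degenerate (middle angle at +/-90 degrees)."""


class UnusableTrialError(KneePCAError):
    """A raw trial cannot be processed (e.g. an all-missing channel)."""


class NoCompleteCycleError(KneePCAError):
    """Fewer than two heel strikes: no complete gait cycle in the stream."""


class DegenerateCovarianceError(KneePCAError):
    """Covariance rank < 2: angles carry no correctable structure."""


class CycleFormatError(KneePCAError, ValueError):
    """A cycle CSV file violates the exchange format."""
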