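"""Exception hierarchy."""


class RarePSError(Exception):
    """Base class for all package errors."""


class ScenarioError(RarePSError):
    """Invalid scenario configuration (e.g. non-PSD covariance, unset calibration)."""


class CalibrationError(RarePSError):
    """Root search for a calibrated constant failed to bracket or converge."""


class EstimationError(RarePSError):
    """An estimator received a sample it cannot be fitted on."""
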