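"""Exception types shared across the package."""


class ParameterError(ValueError):
    """A parameter violates its documented precondition."""


class InsufficientDataError(ValueError):
    """Too few observations to run the requested analysis."""


class KernelConstructionError(RuntimeError):
    """Numerical construction of an offspring dispersal kernel failed."""


class CalibrationError(RuntimeError):
    """Detector calibration did not meet the required fit quality."""


class ResolutionError(RuntimeError):
    """Evaluation grid too coarse for the requested kernel width."""
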