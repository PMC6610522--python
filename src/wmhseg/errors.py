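"""Exception hierarchy shared across the package."""


class WMHSegError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(WMHSegError, ValueError):
    """A configuration value is outside its admissible range."""


class ContractViolation(WMHSegError, ValueError):
    """Inputs violate a documented precondition (shape/alignment mismatch etc.)."""


class AlignmentError(ContractViolation):
    """Volumes of one bundle do not share shape and affine."""


class DegenerateSliceError(WMHSegError, ValueError):
    """A slice cannot be processed (empty brain mask, zero variance...)."""


class PlacementError(WMHSegError, RuntimeError):
    """A synthetic lesion could not be placed after bounded retries."""
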