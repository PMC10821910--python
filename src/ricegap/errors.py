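"""Exception hierarchy for ricegap."""


class RicegapError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(RicegapError, ValueError):
    """An input parameter violates its documented domain."""


class CycleIncompleteError(RicegapError, RuntimeError):
    """Weather series ends before the crop reaches maturity."""


class CalibrationInfeasibleError(RicegapError, RuntimeError):
    """Phenology calibration cannot reach the target duration within rate bounds."""


class SelectionError(RicegapError, ValueError):
    """Reference-buffer selection received no usable candidates."""


class AccountingError(RicegapError, ValueError):
    """A supply/demand accounting identity produced an impossible value."""
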