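"""Exception hierarchy shared across the simulator."""


class VestibsimError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(VestibsimError, ValueError):
    """A waveform or run specification violates its invariants."""


class GeometryError(VestibsimError, ValueError):
    """Anatomy construction produced or received impossible geometry."""


class SingularityError(VestibsimError, ValueError):
    """A field was requested at (or too close to) a source location."""


class NumericalStabilityError(VestibsimError, RuntimeError):
    """The cable integration diverged; the message names the offending dt."""


class AlignmentError(VestibsimError, ValueError):
    """Time grids of results that must be combined do not match."""


class IncompatibleFileError(VestibsimError, ValueError):
    """A serialized artifact cannot be read back (truncated or wrong version)."""
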