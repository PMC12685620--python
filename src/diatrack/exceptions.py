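"""Exception hierarchy shared across the package."""


class DiatrackError(Exception):
    """Base class for all package-specific errors."""


# -- geometry ---------------------------------------------------------------

class PointAtSourceError(DiatrackError):
    """The 3D point coincides with the x-ray source."""


class BehindSourceError(DiatrackError):
    """The 3D point lies behind the source, so its projection is undefined."""


class ParallelRaysError(DiatrackError):
    """Triangulation was attempted on (numerically) parallel rays."""


class DegenerateEpipoleError(DiatrackError):
    """The back-projected ray collapses to a single point in the other view."""


# -- phantom ----------------------------------------------------------------

class BadConfigError(DiatrackError):
    """A simulation configuration value is out of its valid range."""


class ApexOutsideImageError(DiatrackError):
    """The projected diaphragm apex falls outside the detector frame."""


# -- imaging ----------------------------------------------------------------

class BadDimsError(DiatrackError):
    """Image dimensions do not match the expected detector format."""


class EmptyWindowError(DiatrackError):
    """The search window admits no valid template placement."""


class ZeroVarianceError(DiatrackError):
    """Correlation is undefined: template or all candidate patches constant."""


class MissingEpipolarError(DiatrackError):
    """A lateral-region search window was requested without an epipolar line."""


class LostTrackError(DiatrackError):
    """Match score stayed below the floor for too many consecutive frames."""


# -- motion -----------------------------------------------------------------

class TooShortError(DiatrackError):
    """The signal is too short for the requested operation."""


class NoCycleError(DiatrackError):
    """No qualifying trough/peak pair found in the analysis window."""


class DegenerateBreathingRangeError(DiatrackError):
    """End-expiratory and end-inspiratory signal values coincide."""


class TooFewSamplesError(DiatrackError):
    """Not enough samples to fit the correlation model."""


# -- evaluation -------------------------------------------------------------

class MisalignedTimesError(DiatrackError):
    """Predicted and ground-truth trajectories are not on the same time grid."""


class EmptyError(DiatrackError):
    """An empty input where at least one sample is required."""


class NonpositiveAmplitudeError(DiatrackError):
    """Reduction ratio requested with a nonpositive motion amplitude."""
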