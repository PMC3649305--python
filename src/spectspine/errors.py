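"""Exception hierarchy for spectspine.

Every failure mode of the extraction pipeline maps to a distinct exception
class so that callers (and the command-line interface) can react to the
stage that failed.  The CLI assigns one exit code per class.
"""


class SpectSpineError(Exception):
    """Base class for all spectspine errors."""

    exit_code = 1


class FormatError(SpectSpineError):
    """A volume header or sidecar is missing, corrupt or inconsistent."""

    exit_code = 2


class SizeMismatchError(FormatError):
    """Declared shape/dtype does not match the image file's byte length."""

    exit_code = 3


class DegenerateInputError(SpectSpineError):
    """Input is too degenerate for the operation (e.g. constant volume)."""

    exit_code = 4


class ComputationError(SpectSpineError):
    """A numeric step failed (e.g. non-real moment-preserving roots)."""

    exit_code = 5


class LandmarkNotFoundError(SpectSpineError):
    """A required anatomical reference node could not be located."""

    exit_code = 6


class LegSeparationError(LandmarkNotFoundError):
    """The leg count profile did not separate into exactly two groups."""

    exit_code = 7


class PelvisNotFoundError(LandmarkNotFoundError):
    """Region growing found no pelvis seeds in the hip-joint slice."""

    exit_code = 8


class NonConvergenceError(SpectSpineError):
    """Graph clustering exceeded its iteration cap.

    Carries the merge log accumulated so far in ``merge_log``.
    """

    exit_code = 9

    def __init__(self, message, merge_log=None):
        super().__init__(message)
        self.merge_log = merge_log or []


class PhantomSpecError(SpectSpineError):
    """A phantom specification describes impossible geometry."""

    exit_code = 10
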