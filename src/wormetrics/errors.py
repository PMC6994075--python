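"""Exception hierarchy for worm measurement failures.

Every documented failure mode maps onto a distinct exception class so that
batch runs can record a structured status per worm instead of aborting.
"""


class WormetricsError(Exception):
    """Base class for all failures raised by this package."""


class NoContrastError(WormetricsError):
    """Image (or all channels) is constant; nothing can be thresholded."""


class NoObjectError(WormetricsError):
    """Thresholding produced an empty foreground."""


class ObjectEliminatedError(WormetricsError):
    """Morphological cleanup removed the object entirely."""


class UnsupportedChannelsError(WormetricsError):
    """Image has a channel count other than 1 or 3."""

    def __init__(self, n_channels: int):
        self.n_channels = n_channels
        super().__init__(f"unsupported channel count: {n_channels} (expected 1 or 3)")


class SelfOverlapError(WormetricsError):
    """Skeleton forms a closed loop: the worm overlaps itself."""


class DegenerateWormError(WormetricsError):
    """Skeleton too short to define a midline (e.g. a near-circular blob)."""


class SelfProximityError(WormetricsError):
    """Two parts of the midline come close enough that perpendicular
    profiles become ambiguous; tracing cannot proceed reliably."""


class EndExtensionError(WormetricsError):
    """Ray from a spine end never crossed the worm outline."""


class RadiiFailureError(WormetricsError):
    """Too many width measurements were missing to trust the profile."""
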