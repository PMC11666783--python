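"""Exception hierarchy shared across the package."""


class MeiotrackError(Exception):
    """Base class for all package-specific errors."""


class AmbiguousAxisError(MeiotrackError):
    """Orientation scatter has (near-)tied leading eigenvalues: no unique axis."""


class EmptyForegroundError(MeiotrackError):
    """A segmentation/thresholding step produced no foreground voxels."""


class FlatImageError(MeiotrackError):
    """An image has no contrast, so correlation/thresholding is undefined."""


class InfeasibleModelError(MeiotrackError):
    """An ILP constraint system admits no solution.

    The message names the constraint family believed responsible.
    """


class StitchError(MeiotrackError):
    """Track batches could not be stitched unambiguously."""
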