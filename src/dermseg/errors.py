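"""Exception types shared across the segmentation pipeline."""


class DermsegError(Exception):
    """Base class for all package-specific errors."""


class ShapeError(DermsegError, ValueError):
    """An array does not have the expected dimensionality or shape."""


class ParameterError(DermsegError, ValueError):
    """A tunable parameter is outside its legal range."""


class NoLesionError(DermsegError, RuntimeError):
    """The saliency map is flat, so no threshold separates lesion from skin.

    Raised when the input collapses to a single color cluster (or all
    clusters receive identical saliency), e.g. for constant-color images.
    """


class FixtureSpecError(DermsegError, ValueError):
    """A synthetic fixture specification is internally inconsistent."""
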