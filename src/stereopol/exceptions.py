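"""Exception hierarchy for stereopol."""


class StereopolError(Exception):
    """Base class for all stereopol errors."""


class InfeasibleDensityError(StereopolError, ValueError):
    """Requested dot density is >= 1 and cannot be realised."""


class GeometryError(StereopolError, ValueError):
    """Dot geometry incompatible with the image (e.g. dot larger than image)."""


class PackingInfeasibleError(StereopolError, RuntimeError):
    """Non-overlapping dot placement failed repeatedly; packing too dense.

    Carries the coverage achieved before the generator gave up.
    """

    def __init__(self, message: str, achieved_density: float):
        super().__init__(message)
        self.achieved_density = achieved_density


class DegenerateImageError(StereopolError, ValueError):
    """An image has (near-)zero variance and cannot be normalised/correlated."""


class SequencingError(StereopolError, RuntimeError):
    """Operations applied in an invalid order (e.g. polarity conversion after
    normalisation)."""


class ProvenanceError(StereopolError, ValueError):
    """Operation requires per-pixel dot provenance that the pair does not carry."""


class RangeError(StereopolError, ValueError):
    """Displacement/lag outside the range where images overlap."""


class NormalizationError(StereopolError, RuntimeError):
    """Tuning-curve baseline is degenerate (mean uncorrelated response ~ 0)."""
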