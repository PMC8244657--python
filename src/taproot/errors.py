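"""Exception types raised across the pipeline."""


class TaprootError(Exception):
    """Base class for all package-specific errors."""


class NoForegroundError(TaprootError):
    """No connected component survived thresholding and cleaning."""


class AmbiguousForegroundError(TaprootError):
    """Two candidate components have areas within 10% of each other."""


class DegenerateSegmentError(TaprootError):
    """Consecutive contour points coincide; curvature is undefined."""


class WalkStalledError(TaprootError):
    """The midline walk failed to reach the shoulder row.

    Carries the last visited position as ``last_position``.
    """

    def __init__(self, message, last_position=None):
        super().__init__(message)
        self.last_position = last_position


class NormalEscapeError(TaprootError):
    """A width-sampling ray exited the raster before reaching background."""


class InsufficientDataError(TaprootError):
    """Too few labeled examples to train the de-tip model."""


class UnbalancedDesignError(TaprootError):
    """A half-diallel table is missing cross/replicate cells.

    Carries the missing ``(parent_i, parent_j, rep)`` cells as ``missing``.
    """

    def __init__(self, message, missing=None):
        super().__init__(message)
        self.missing = missing or []


class SingularDesignError(TaprootError):
    """Fewer than four parents: Method IV effects are not estimable."""


class MalformedNameError(TaprootError):
    """A mask filename does not follow ``{genotype}_{rootid}_{barpx}.png``.

    Carries the offending token as ``token``.
    """

    def __init__(self, message, token=None):
        super().__init__(message)
        self.token = token
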