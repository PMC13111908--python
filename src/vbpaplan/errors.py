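"""Exception hierarchy for the vBPA planning toolkit."""


class VbpaError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(VbpaError, ValueError):
    """A parameter violates its contract (range, sign, count)."""


class InvalidGeometryError(VbpaError):
    """Degenerate or inconsistent geometric input."""


class OutOfRangeError(VbpaError):
    """A lesion, balloon or station lies outside the vessel extent."""


class TopologyError(VbpaError):
    """Vessel tree specification is cyclic, disconnected or multi-rooted."""


class NoHealthyReferenceError(VbpaError):
    """Morphology restoration has no healthy radius samples to fit."""


class ConvergenceError(VbpaError):
    """Iterative solve failed to reach tolerance.

    Carries the residual history so callers can inspect stagnation.
    """

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = list(residuals) if residuals is not None else []


class GradientError(VbpaError):
    """Field too small along some axis to form finite differences."""


class EmptyRegionError(VbpaError):
    """A surface region is empty (after exclusion or clipping)."""


class SamplingError(VbpaError):
    """A surface face or probe point lies outside the field grid."""


class UndefinedCompositionError(VbpaError):
    """Vortex composition undefined because the low-band volume is zero."""


class SegmentLookupError(VbpaError, KeyError):
    """Named tree segment does not exist."""


class PipelineStageError(VbpaError):
    """A pipeline stage failed; carries the stage tag."""

    def __init__(self, stage, message):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
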