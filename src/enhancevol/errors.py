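"""Exception hierarchy for the enhancement-volumetry pipeline.

Every stage of :func:`enhancevol.enhancement_core.quantify` raises a
subclass of :class:`EnhancevolError`; :class:`PipelineStageError` wraps a
stage failure and names the stage so CLI users can see where a run died.
"""


class EnhancevolError(Exception):
    """Base class for all package errors."""


class VolumeReadError(EnhancevolError):
    """A volume could not be read (missing slices, inconsistent geometry...)."""


class GridMismatchError(EnhancevolError):
    """Two images expected on the same voxel grid are not."""


class RoiError(EnhancevolError):
    """An ROI is empty, on the wrong grid, or violates role constraints."""


class RegistrationError(EnhancevolError):
    """Registration failed to converge or produced a degenerate transform."""


class ThresholdError(EnhancevolError):
    """The enhancement threshold could not be derived (e.g. mucosa shows
    no net enhancement, or the trim removes every value)."""


class PipelineStageError(EnhancevolError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
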