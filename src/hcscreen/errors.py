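"""Exception hierarchy shared across the package."""


class ScreenError(Exception):
    """Base class for all hcscreen errors."""


class LayoutError(ScreenError):
    """Requested wells do not fit the available plate geometry."""


class PlacementError(ScreenError):
    """Cell phantoms could not be placed without violating spacing."""


class InsufficientControlsError(ScreenError):
    """Fewer than two usable control wells of a required role."""


class DegenerateControlsError(ScreenError):
    """Positive and negative control means coincide; normalization undefined."""


class InsufficientDataError(ScreenError):
    """Not enough usable data points for the requested fit."""


class PipelineStageError(ScreenError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[stage: {stage}] {message}")
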