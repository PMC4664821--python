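"""Exception types shared across the pipeline.

Trial-level detection failures are distinct from parameter errors so that a
batch run can flag the offending trial and keep going.
"""


class ParameterError(ValueError):
    """An argument violates a documented precondition."""


class InitiationNotDetectedError(RuntimeError):
    """No qualifying velocity rise found; the trial is flagged, not dropped."""


class DegenerateCoordinationError(RuntimeError):
    """A correlation input has zero variance (or no admissible lag) in the window."""


class MissingCellError(ValueError):
    """The repeated-measures design is incomplete; lists the missing cells."""
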