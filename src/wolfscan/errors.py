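"""Exception hierarchy shared across the pipeline stages."""


class WolfscanError(Exception):
    """Base class for all package-specific errors."""


class UndefinedStatisticError(WolfscanError):
    """A statistic is undefined for the given input (e.g. zero variance)."""


class DegenerateNullError(WolfscanError):
    """The null expectation of a scan statistic is degenerate.

    Raised e.g. when the median sister-outgroup branch length is zero, in
    which case the PBE expectation cannot be scaled; the remedy is to drop
    invariant sites before the scan.
    """


class PipelineOrderError(WolfscanError):
    """A stage was invoked before its prerequisite stage."""


class PipelineError(WolfscanError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
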