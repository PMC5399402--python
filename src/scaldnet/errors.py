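"""Typed exceptions raised across the pipeline."""

from __future__ import annotations


class ScaldnetError(Exception):
    """Base class for all package errors."""


class ValidationError(ScaldnetError):
    """Input data or configuration violates a documented contract."""


class DuplicateIdError(ValidationError):
    """Duplicate variable or sample identifiers.

    Carries the offending identifiers so callers can report them.
    """

    def __init__(self, kind: str, ids):
        self.kind = kind
        self.ids = sorted(ids)
        super().__init__(f"duplicate {kind} id(s): {', '.join(map(str, self.ids))}")


class SizingError(ValidationError):
    """A request exceeds the available problem size (e.g. more planted
    genes than genes to generate, or more components than the data rank)."""


class AlignmentError(ValidationError):
    """Blocks or metadata do not share the same sample set/order."""


class PipelineError(ScaldnetError):
    """A pipeline stage failed; names the stage and the underlying cause."""

    def __init__(self, stage: str, cause: BaseException | str):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
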