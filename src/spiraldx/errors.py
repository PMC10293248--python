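"""Typed exceptions shared across the package.

Every malformed input raises one of these; no operation returns a partially
constructed object.
"""


class SpiralDxError(Exception):
    """Base class for all package errors."""


class FormatError(SpiralDxError):
    """A file does not conform to the expected on-disk layout."""


class ValidationError(SpiralDxError):
    """Structurally well-formed input violates a domain invariant."""


class DomainError(SpiralDxError, ValueError):
    """A parameter is outside its mathematical domain."""


class CohortError(SpiralDxError):
    """A cohort manifest is inconsistent (duplicate ids, dangling files...)."""


class PipelineError(SpiralDxError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, message: str, participant_id: str | None = None):
        self.stage = stage
        self.participant_id = participant_id
        detail = f"[stage={stage}]"
        if participant_id is not None:
            detail += f" [participant={participant_id}]"
        super().__init__(f"{detail} {message}")
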