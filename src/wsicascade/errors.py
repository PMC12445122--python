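"""Exception hierarchy shared across the pipeline.

Exit-code mapping for the CLI: ValidationError -> 2, DependencyError -> 3.
"""


class WsiCascadeError(Exception):
    """Base class for all package errors."""


class ValidationError(WsiCascadeError):
    """Invalid input, configuration, or precondition violation."""


class TilingError(ValidationError):
    """Slide cannot be tiled (e.g., smaller than the tile size)."""


class ConflictError(ValidationError):
    """Two inconsistent values supplied for the same grid cell."""


class DependencyError(WsiCascadeError):
    """A pipeline stage was invoked before the stages it depends on."""
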