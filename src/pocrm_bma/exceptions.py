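"""Package exceptions."""


class InvalidParameterError(ValueError):
    """A configuration or input value violates a precondition."""


class QuadratureError(RuntimeError):
    """Numerical integration failed; carries the ordering index when known."""

    def __init__(self, message: str, ordering: int | None = None):
        super().__init__(message)
        self.ordering = ordering


class StreamExhaustedError(RuntimeError):
    """A per-dose response stream ran out of entries during a replay."""
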