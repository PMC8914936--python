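"""Exception types shared across the package."""


class LimbIntentError(Exception):
    """Base class for all package-specific errors."""


class NotReadyError(LimbIntentError):
    """Raised when a result cannot be produced *yet* (e.g. fewer than two
    motion units have closed), as opposed to the input being invalid.

    Callers running on a live stream should treat this as "wait for more
    data", not as a failure.
    """


class GenerationError(LimbIntentError):
    """Raised by the synthetic-trace generator when a script cannot produce
    a trace that respects the segmentation thresholds (e.g. a move phase too
    shallow to ever exceed the movement threshold)."""


class SchemaError(LimbIntentError):
    """Raised when an external file (trace CSV, template JSON, model JSON)
    does not match its documented schema."""
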