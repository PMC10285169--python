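"""Exception types shared across the pipeline."""


class IgTraceError(Exception):
    """Base class for all igtrace errors."""


class FormatError(IgTraceError):
    """An external file violates its expected dialect or schema."""


class InputError(IgTraceError):
    """In-memory inputs to an operation violate its preconditions."""


class ConfigurationError(IgTraceError):
    """A simulation or pipeline configuration is internally inconsistent."""


class AnnotationError(IgTraceError):
    """Cell metadata cannot be mapped to a cell-type label."""
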