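"""Exception hierarchy.

All domain validation failures derive from :class:`ParameterError` so callers
can catch one type at the CLI boundary; more specific subclasses exist where
the failure mode is worth distinguishing programmatically.
"""


class ParameterError(ValueError):
    """A model parameter is outside its mathematical domain."""


class LayoutError(ParameterError):
    """A batch layout violates the m >= 2, c >= 1 constraints."""


class AnnotationError(ParameterError):
    """A vesicle annotation is degenerate or out of image bounds."""


class ProfileError(ParameterError):
    """A line profile is too short or otherwise unusable."""


class NoEdgeError(RuntimeError):
    """A profile is flat: no intensity edge to locate."""


class SchemaError(ValueError):
    """A tabular file does not match its declared column schema."""
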