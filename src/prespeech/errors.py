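"""Exception hierarchy.

Readers and validators fail loudly with the location of the offending
record; metric denominators depend on completeness, so nothing is ever
silently skipped.
"""


class PrespeechError(Exception):
    """Base class for all package errors."""


class ValidationError(PrespeechError):
    """A domain-type invariant was violated."""


class FormatError(PrespeechError):
    """A file does not match its expected schema (missing column/field)."""


class ParseError(PrespeechError):
    """A cell or field could not be parsed; message carries the location."""


class GeometryError(PrespeechError):
    """An AOI polygon is degenerate or self-intersecting."""


class ConfigError(PrespeechError):
    """An invalid configuration value or duplicate AOI label."""


class AnnotationError(PrespeechError):
    """A token lacks an annotation a rule needs (e.g. timing)."""


class DesignError(PrespeechError):
    """A statistical design is incomplete or unsupported."""


class PipelineError(PrespeechError):
    """A pipeline stage failed; message names the stage and record."""
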