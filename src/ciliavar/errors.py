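"""Exception hierarchy.

``FormatError`` covers structural problems in an input file (missing columns,
unparseable cells); ``ValidationError`` covers values that parse but violate a
domain invariant; ``InsufficientAnnotationError`` is raised when a variant
carries too little predictor annotation to be classified at all.
"""


class CiliavarError(Exception):
    """Base class for all package errors."""


class FormatError(CiliavarError):
    """An input file is structurally malformed."""


class ValidationError(CiliavarError):
    """A parsed value violates a domain invariant."""


class InsufficientAnnotationError(CiliavarError):
    """No in-silico predictor is available for a variant that needs one."""
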