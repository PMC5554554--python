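"""Exception hierarchy.

Every error raised by the library derives from :class:`TPDAError`, so callers
(and the CLI) can distinguish library failures from programming errors while
still catching narrowly by category.
"""


class TPDAError(Exception):
    """Base class for all tpdanet errors."""


class UnknownNameError(TPDAError, KeyError):
    """A variable, node or sample name does not exist or is duplicated."""


class DataFormatError(TPDAError, ValueError):
    """Malformed input data (non-numeric cell, missing value, bad edge list)."""


class SizeError(TPDAError, ValueError):
    """Input too small or dimensions inconsistent."""


class ParameterError(TPDAError, ValueError):
    """Invalid parameter value (bin count, threshold, denominator)."""


class StructureError(TPDAError, ValueError):
    """Invalid graph structure (cycle, self-loop, duplicate edge)."""
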