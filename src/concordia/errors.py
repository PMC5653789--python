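"""Exception hierarchy.

Validation problems (bad configs, malformed files, contract violations on
inputs) raise :class:`ValidationError`; anything else propagates as the
underlying exception.  The CLI maps ValidationError to exit code 2 and other
errors to exit code 1.
"""


class ConcordiaError(Exception):
    """Base class for package errors."""


class ValidationError(ConcordiaError, ValueError):
    """An input, file, or configuration violates a stated precondition."""
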