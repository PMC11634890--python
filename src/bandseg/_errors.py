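"""Exception hierarchy.

``ValidationError`` marks bad user input (CLI exit code 2); everything else
raised by the package is a plain ``BandsegError`` (exit code 1).
"""


class BandsegError(Exception):
    """Base class for all errors raised by bandseg."""


class ValidationError(BandsegError, ValueError):
    """Invalid input data or configuration."""
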