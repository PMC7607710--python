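"""Exception hierarchy.

Each pipeline stage raises a subclass of :class:`CarrierScreenError` so a
caller can map failure classes to distinct exit codes.
"""


class CarrierScreenError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(CarrierScreenError, ValueError):
    """A document or token could not be parsed; the message names the offender."""


class ValidationError(CarrierScreenError, ValueError):
    """Parsed input violates a domain invariant (duplicate keys, range violations,
    dangling references)."""
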