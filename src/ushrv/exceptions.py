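"""Exception hierarchy for ushrv."""


class UshrvError(Exception):
    """Base class for all package errors."""


class ParseError(UshrvError):
    """A file row could not be parsed; message names the offending line."""


class ValidationError(UshrvError):
    """Data violate an invariant (e.g. non-positive RR interval)."""


class ConfigurationError(UshrvError):
    """Parameters are inconsistent or admit no valid output."""


class AlignmentError(UshrvError):
    """Two feature vectors share no usable center-time overlap."""
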