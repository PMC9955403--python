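"""Domain-specific exceptions raised by the processing stages."""


class CGHOFDError(Exception):
    """Base class for all package errors."""


class RecordUnusableError(CGHOFDError):
    """The record is empty or entirely invalid after cleaning."""


class DegenerateSegmentError(CGHOFDError):
    """A segment is constant or otherwise cannot be normalized."""


class SegmentTooShortError(CGHOFDError):
    """A series is shorter than the filter it should pass through."""


class RecordExcludedError(CGHOFDError):
    """No segment of the record survived the gating rules."""


class NoCyclesError(CGHOFDError):
    """No cardiac cycles could be located in the signal."""
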