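"""Exception hierarchy shared across the pipeline."""


class MicrobiodxError(Exception):
    """Base class for all package errors."""


class FormatError(MicrobiodxError):
    """A file could not be parsed in the expected dialect."""


class ValidationError(MicrobiodxError):
    """Parsed data violate a documented invariant."""


class StateError(MicrobiodxError):
    """An operation was called on an object in the wrong state."""
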