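"""Exception hierarchy."""


class UstScreenError(Exception):
    """Base class for all errors raised by this package."""


class InputError(UstScreenError):
    """A required input file is missing or unreadable."""


class ValidationError(UstScreenError):
    """Input data or parameters violate a contract."""
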