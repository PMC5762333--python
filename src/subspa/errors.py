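"""Exception hierarchy shared across modules."""


class SubspaError(Exception):
    """Base class for all errors raised by subspa."""


class InputError(SubspaError):
    """An input file or in-memory object violates a documented invariant."""


class KgmlParseError(InputError):
    """A KGML document could not be parsed."""
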