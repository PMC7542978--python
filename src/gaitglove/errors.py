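"""Exception hierarchy for glove-data handling and analysis stages."""


class GaitGloveError(Exception):
    """Base class for all package errors."""


class FormatError(GaitGloveError):
    """A file does not conform to the documented tabular dialect."""


class ParseError(GaitGloveError):
    """A cell could not be parsed; carries row/column context in the message."""


class ValidationError(GaitGloveError):
    """Data violates a declared invariant (range, shape, metadata)."""


class ChannelLookupError(GaitGloveError, KeyError):
    """A requested channel is not present in the layout."""


class SizeError(GaitGloveError):
    """An operation was asked for more frames/items than available."""


class SpecError(GaitGloveError):
    """A synthetic-generation spec violates its invariants."""


class AnalysisError(GaitGloveError):
    """An analysis operation cannot produce a defined result."""
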