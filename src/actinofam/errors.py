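"""Typed exceptions shared across the package."""


class ActinofamError(Exception):
    """Base class for all package errors."""


class ParseError(ActinofamError):
    """A file could not be parsed; the message names the offending record/line."""


class DuplicateIdError(ParseError):
    """Two records in one collection share an id."""


class IllegalCharacterError(ParseError):
    """A sequence contains a character outside its allowed alphabet."""


class AnnotationError(ActinofamError):
    """A precursor could not be segmented into signal/propeptide/mature."""


class AlignmentError(ActinofamError):
    """Alignment input or post-condition violated."""


class DistanceError(ActinofamError):
    """Distance computation impossible (non-finite input, no shared columns)."""


class RuleError(ActinofamError):
    """A diagnostic-residue rule refers to an unmappable position."""


class StructureError(ActinofamError):
    """A charged structure is degenerate for the requested operation."""


class PipelineError(ActinofamError):
    """A pipeline stage failed; message carries stage name and record."""


class DatasetUnavailableError(ActinofamError):
    """A required external dataset is not present on disk.

    Raised by loaders for data that must be fetched by the user (for example
    the GenBank records of the cloned actinoporin precursors); the message
    states where the loader looked and what to place there.
    """
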