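"""Exception hierarchy shared across the pipeline."""


class DelscapeError(Exception):
    """Base class for all pipeline errors."""


class FormatError(DelscapeError):
    """A file does not conform to the expected format (missing column, bad field)."""


class ValidationError(DelscapeError):
    """Input records violate a domain invariant (e.g. unmatched blood sample)."""


class ReferenceMismatchError(DelscapeError):
    """A deletion's recorded sequence disagrees with the reference FASTA."""


class ModelError(DelscapeError):
    """The requested model term/stratum cannot be formed from the data."""
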