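"""Exception hierarchy for barcode-gap analyses.

Every error raised by this package derives from :class:`BarcodeError`, so
callers can catch one type at a pipeline boundary while tests can assert
on the specific failure mode.
"""


class BarcodeError(Exception):
    """Base class for all errors raised by barcodegap."""


class AlignmentError(BarcodeError):
    """Sequences that should form an aligned matrix do not (unequal lengths,
    too few records)."""


class AlphabetError(BarcodeError):
    """A sequence contains a character outside the IUPAC nucleotide
    alphabet (plus gap)."""


class MetadataError(BarcodeError):
    """Specimen-metadata table is malformed: missing required columns,
    empty, or duplicate specimen IDs."""


class JoinError(BarcodeError):
    """Alignment and metadata specimen-ID sets are not in one-to-one
    correspondence."""


class DegenerateInputError(BarcodeError):
    """Input is valid in form but carries no usable signal (e.g. an
    alignment of only gaps/N, or all-identical distances)."""


class IncomparablePairError(BarcodeError):
    """A sequence pair shares no alignment column where both members carry
    an unambiguous base."""


class SaturationError(BarcodeError):
    """Observed transition/transversion proportions fall outside the domain
    of the K2P correction (logarithm argument <= 0)."""


class PartitionError(BarcodeError):
    """A distance partition cannot support the requested analysis (e.g.
    a single species leaves the interspecific set empty)."""


class ConfigError(BarcodeError):
    """Invalid simulation or pipeline configuration."""
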