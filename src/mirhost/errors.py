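"""Exception hierarchy for mirhost."""


class MirhostError(Exception):
    """Base class for all mirhost-specific errors."""


class Gff3ParseError(MirhostError):
    """A GFF3 stream violates the format or its referential integrity."""


class TableFormatError(MirhostError):
    """A tabular input (DE table, sequence table, target map) is unusable."""


class GmtFormatError(MirhostError):
    """A GMT gene-set stream violates the format."""


class SequenceConflictError(MirhostError):
    """The same mature id was supplied with two different sequences."""


class InvalidConfigError(MirhostError):
    """A simulation configuration is internally inconsistent or infeasible."""
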