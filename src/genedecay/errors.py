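"""Exception hierarchy for genedecay.

Every error raised by the library derives from :class:`GeneDecayError`, so
callers (and the CLI) can distinguish validation failures from genuine bugs.
"""


class GeneDecayError(Exception):
    """Base class for all genedecay errors."""


class AlignmentShapeError(GeneDecayError):
    """Sequences in an alignment do not have equal length (or the file is malformed)."""


class MissingReferenceError(GeneDecayError):
    """The designated reference id is absent from the alignment."""


class MissingSequenceError(GeneDecayError):
    """A requested sequence id is absent from the alignment."""


class AlphabetError(GeneDecayError):
    """A residue outside the accepted nucleotide alphabet was found."""


class ModelConsistencyError(GeneDecayError):
    """A gene model violates its structural invariants (exon/intron layout)."""


class CoordinateRangeError(GeneDecayError):
    """A codon index or position falls outside the mapped coordinate range."""


class EventConsistencyError(GeneDecayError):
    """Disruption events passed together do not belong to a single sequence."""


class NotAnAlternativeError(GeneDecayError):
    """Retention prediction was requested for the annotated acceptor (offset 0)."""


class UndefinedTestError(GeneDecayError):
    """The relative-rate test is undefined (no unique differences in either taxon)."""


class SimConfigError(GeneDecayError):
    """A simulation configuration is invalid (bad root sequence, unknown branch, ...)."""
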