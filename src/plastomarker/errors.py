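"""Exception hierarchy for plastomarker.

All package-specific failures derive from :class:`PlastomarkerError` so that
callers can catch one base class at pipeline boundaries.
"""


class PlastomarkerError(Exception):
    """Base class for all plastomarker errors."""


class RaggedAlignmentError(PlastomarkerError):
    """Sequences in an alignment do not all have the same length."""


class DuplicateTaxonError(PlastomarkerError):
    """Two records share the same taxon label."""


class EmptyInputError(PlastomarkerError):
    """An input file or sequence set contains no usable data."""


class AlphabetError(PlastomarkerError):
    """A sequence contains a character outside the nucleotide alphabet."""


class PartitionConflictError(PlastomarkerError):
    """Partition intervals overlap, fall outside the alignment, or clash."""


class CoordinateError(PlastomarkerError):
    """An interval is inverted, empty, or out of range."""


class TreeParseError(PlastomarkerError):
    """A Newick string could not be parsed."""


class LabelError(PlastomarkerError):
    """Taxon labels of a tree/alignment/group do not line up."""


class ConfigError(PlastomarkerError):
    """A configuration value violates its contract."""


class SaturationError(PlastomarkerError):
    """A p-distance is at or beyond the Jukes-Cantor saturation limit (3/4)."""


class IncomparablePairError(PlastomarkerError):
    """A pair of sequences shares no comparable (non-missing) positions."""
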