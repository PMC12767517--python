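"""Exception hierarchy.

Every error raised by the package derives from :class:`EdgeticError` so callers
can catch the whole family at a pipeline boundary.
"""


class EdgeticError(Exception):
    """Base class for all package errors."""


class StructureFormatError(EdgeticError):
    """The structure file could not be parsed as mmCIF or PDB."""


class ChainNotFoundError(EdgeticError):
    """A requested chain id is absent from the structure."""


class DegenerateInputError(EdgeticError):
    """An input is structurally empty (e.g. a chain with no residues)."""


class ReferenceMismatchError(EdgeticError):
    """The stated wild-type residue does not match the sequence."""


class DimensionError(EdgeticError):
    """Array shapes are inconsistent."""


class AlignmentError(EdgeticError):
    """Embedding length does not match chain length."""


class InsufficientDataError(EdgeticError):
    """Too few records to fit (e.g. a normalizer on <2 encodings)."""


class SchemaError(EdgeticError):
    """A tabular input violates its documented schema."""


class DataError(EdgeticError):
    """A dataset is empty or otherwise unusable."""


class DegenerateClassError(EdgeticError):
    """Class weighting requested but only one class is present."""


class RoleError(EdgeticError):
    """The mutation site lies on the partner chain; flip roles first."""


class ConfigError(EdgeticError):
    """Inconsistent model or run configuration."""


class CompatibilityError(EdgeticError):
    """A model checkpoint is incompatible with the requested configuration."""


class PartitionError(EdgeticError):
    """Fewer clusters than folds; a group partition is impossible."""


class UndefinedMetricError(EdgeticError):
    """A metric (e.g. ROC AUC) is undefined for the given labels."""


class UndefinedStatisticError(EdgeticError):
    """A statistic is undefined on this input (e.g. E with both rates zero)."""


class SpecError(EdgeticError):
    """A synthetic-data specification is infeasible."""
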