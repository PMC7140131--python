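"""Exception hierarchy shared across the package."""


class TmcontactError(Exception):
    """Base class for all package-specific errors."""


class ParseError(TmcontactError, ValueError):
    """Malformed input file (FASTA, PSSM, topology, PDB ...)."""


class AlignmentShapeError(ParseError):
    """Alignment rows do not all share the same number of columns."""


class ChainNotFoundError(TmcontactError, KeyError):
    """Requested chain is absent from the coordinate file."""


class ContractError(TmcontactError, ValueError):
    """A documented precondition of an operation was violated."""


class ConfigurationError(TmcontactError, ValueError):
    """Unknown method name, invalid model/synthetic configuration, ..."""


class DegenerateColumnError(TmcontactError, ValueError):
    """No alignment row is ungapped in both requested columns."""


class MissingAtomError(TmcontactError, ValueError):
    """A residue lacks the atoms a distance definition requires."""


class TableLookupError(TmcontactError, KeyError):
    """Element missing from the van der Waals radius table."""


class ConsistencyError(TmcontactError, ValueError):
    """Length mismatch between sequence, topology, PSSM or MSA inputs."""


class TrainingError(TmcontactError, ValueError):
    """Dataset unusable for training (e.g. single-class labels)."""
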