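"""Exception hierarchy for pocketeval."""


class PocketEvalError(Exception):
    """Base class for all pocketeval errors."""


class FormatError(PocketEvalError):
    """A file could not be parsed under the declared format."""


class EmptyStructureError(PocketEvalError):
    """A structure file contained no usable model/atoms."""


class MappingError(PocketEvalError):
    """A residue-number mapping table is inconsistent or incomplete."""


class InvariantError(PocketEvalError):
    """A domain-type invariant was violated."""


class DegenerateGeometryError(PocketEvalError):
    """Input coordinates are rank-deficient for the requested operation."""


class UndefinedResultError(PocketEvalError):
    """The requested quantity is undefined for this input (e.g. empty set)."""
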