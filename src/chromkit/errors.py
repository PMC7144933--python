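"""Exception hierarchy shared across chromkit modules."""


class ChromkitError(Exception):
    """Base class for all chromkit errors."""


class PDBParseError(ChromkitError):
    """A PDB record could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class EmptyStructureError(ChromkitError):
    """File contained no atoms."""


class StructuralMismatchError(ChromkitError):
    """Frames or selections disagree on atom counts."""


class SelectionSyntaxError(ChromkitError):
    """Selection expression failed to parse; carries the character position."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"position {position}: {message}"
        super().__init__(message)


class SelectionEmptyError(ChromkitError):
    """A selection that must be non-empty resolved to zero atoms."""


class DegenerateGeometryError(ChromkitError):
    """Geometry is ill-defined (zero vector, collinear plane points, ...)."""


class ParameterError(ChromkitError):
    """An operation parameter is out of its valid domain."""


class GridMismatchError(ChromkitError):
    """Two distributions do not share a common bin grid."""


class EmptyInputError(ChromkitError):
    """An input series/table is empty where data is required."""


class CoverageError(ChromkitError):
    """Umbrella windows do not overlap over the requested range."""


class ConvergenceError(ChromkitError):
    """Self-consistent iteration failed to converge; carries last residual."""

    def __init__(self, message: str, residual: float | None = None):
        self.residual = residual
        super().__init__(message)


class BootstrapInstabilityError(ChromkitError):
    """Too many bootstrap trials failed to produce a solution."""


class ProbeResolutionError(ChromkitError):
    """A probe-atom rule did not resolve to exactly one atom."""


class NoOverlapError(ChromkitError):
    """Predicted and experimental tables share no residues."""


class SchemaError(ChromkitError):
    """A tabular input is missing required columns."""


class MatrixValidityError(ChromkitError):
    """A distance matrix is not symmetric/non-negative/zero-diagonal."""


class ConstructionError(ChromkitError):
    """A synthetic-geometry request is geometrically impossible."""
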