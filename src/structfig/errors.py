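"""Exception hierarchy shared by all structfig modules.

Every domain failure derives from :class:`StructfigError` so the CLI can
map it to a nonzero exit status with a categorized message.
"""


class StructfigError(Exception):
    """Base class for all structfig domain errors."""


class PDBParseError(StructfigError):
    """A coordinate file could not be parsed (malformed field, no atoms)."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class EmptyStructureError(PDBParseError):
    """Input contained no ATOM/HETATM records."""


class CoordinateOverflowError(StructfigError):
    """A coordinate does not fit the fixed-width 8.3 PDB field."""


class ChainNotFoundError(StructfigError):
    """A requested chain identifier is absent from the model."""


class SelectionSyntaxError(StructfigError):
    """A selection expression violates the 'type: target, ...' grammar."""


class UnknownSelectionTypeError(SelectionSyntaxError):
    """Selection level keyword outside the closed keyword set."""


class PairingError(StructfigError):
    """Residue correspondence prerequisites are not met."""


class TooFewPairsError(PairingError):
    """Fewer than 3 residue pairs; superposition is underdetermined."""


class DegenerateGeometryError(StructfigError):
    """Point set of rank < 2; the optimal rotation is not unique."""


class ColoringError(StructfigError):
    """Invalid color-mapping request (bad range, non-positive radius...)."""


class RenderError(StructfigError):
    """Invalid rasterization request (zero-size image...)."""


class LayoutError(StructfigError):
    """Invalid figure plan operation (overlap, unknown label, bad bounds)."""
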