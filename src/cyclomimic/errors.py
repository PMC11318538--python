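"""Exception hierarchy.

``UsageError`` maps to CLI exit code 1 (bad invocation), every other
``CyclomimicError`` subclass to exit code 2 (bad or missing data).
"""


class CyclomimicError(Exception):
    """Base class for all package errors."""


class UsageError(CyclomimicError):
    """Invalid parameters or invocation (CLI exit code 1)."""


class ParameterError(UsageError):
    """A numeric parameter is outside its allowed range."""


class PDBFormatError(CyclomimicError):
    """A PDB record could not be parsed; message names the line number."""


class EmptyStructureError(CyclomimicError):
    """No atoms (or no usable content) in the input."""


class IncompleteBackboneError(CyclomimicError):
    """A residue is missing a required backbone atom."""


class DegenerateGeometryError(CyclomimicError):
    """Coincident or collinear points where full-rank geometry is required."""


class HotspotResolutionError(CyclomimicError):
    """One or more hotspot labels could not be mapped onto the structure."""


class EmptyDatabaseError(CyclomimicError):
    """No usable cyclic peptides were found when building the database."""


class DesignError(CyclomimicError):
    """Mutation plan or grafting inconsistency."""
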