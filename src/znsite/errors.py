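"""Exception hierarchy for znsite."""


class ZnSiteError(Exception):
    """Base class for all znsite errors."""


class ParseError(ZnSiteError):
    """A coordinate file (or serialized library) could not be parsed."""


class EmptyStructureError(ZnSiteError):
    """A parsed structure contains no residues."""


class NotBindingResidueError(ZnSiteError):
    """Residue type is not in the binding-atom dictionary."""


class MissingAtomError(ZnSiteError):
    """A required atom is absent from a residue."""


class DegenerateGeometryError(ZnSiteError):
    """Geometry is degenerate (e.g. collinear binding points)."""


class ContractViolationError(ZnSiteError):
    """An operation was called outside its contract."""


class LibraryVersionError(ZnSiteError):
    """Serialized template library has an unsupported format version."""


class DegenerateFitError(ZnSiteError):
    """Calibration fit is impossible (e.g. single-class labels)."""
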