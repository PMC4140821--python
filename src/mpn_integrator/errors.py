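"""Exception hierarchy for the package."""


class MpnError(Exception):
    """Base class for all package errors."""


class StructureIOError(MpnError):
    """Unreadable/unwritable structure file or unsupported dialect."""


class EmptyStructureError(MpnError):
    """A structure with zero atoms where atoms are required."""


class SelectionError(MpnError):
    """Chain or residue selection referencing absent content."""


class EmptySelectionError(SelectionError):
    """A selection that matches nothing."""


class InvalidPoseError(MpnError):
    """Rotation matrix not orthonormal / not a proper rotation."""


class FormatError(MpnError):
    """Malformed tabular or alignment input."""


class MappingError(MpnError):
    """Alignment reference and structure chain cannot be reconciled."""


class ConstraintError(MpnError):
    """Docking constraint referencing a residue absent from the partners."""


class RadiusError(MpnError):
    """Atom without an assignable van der Waals radius."""


class DegenerateGeometryError(MpnError):
    """Too few or collinear points for a superposition."""


class AlignmentFailureError(MpnError):
    """No usable initial residue correspondence between two chains."""


class AuditError(MpnError):
    """Cross-link audit without any mappable link."""


class UndefinedStatisticError(MpnError):
    """A statistic requested over an empty set."""


class UndefinedInterfaceError(MpnError):
    """Shape complementarity requested for non-touching partners."""


class DensityError(MpnError):
    """Map format, sampling or fitting problem."""


class ConnectivityError(MpnError):
    """Elastic network disconnected at the requested cutoff."""


class ParameterError(MpnError):
    """Invalid numeric parameter value."""


class GenerationError(MpnError):
    """Synthetic-data generation infeasible for the requested spec."""


class PipelineError(MpnError):
    """A pipeline stage failed; message names the stage."""
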