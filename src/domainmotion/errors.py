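"""Exception hierarchy shared across the package."""


class DomainMotionError(Exception):
    """Base class for all package-specific errors."""


class FormatError(DomainMotionError):
    """A structure or trajectory file could not be parsed."""


class ConfigurationError(DomainMotionError):
    """Invalid or incomplete configuration (missing topology, bad spec, ...)."""


class SelectionError(DomainMotionError):
    """An atom selection matched nothing in strict mode, or required atoms are absent."""


class MissingAtomsError(SelectionError):
    """A descriptor's required atoms are absent from the frame.

    Carries the residue identity so trajectory passes can log which residue
    (e.g. an alanine substitution or an unresolved side chain) was at fault.
    """

    def __init__(self, message: str, residues=()):
        super().__init__(message)
        self.residues = tuple(residues)


class GeometryError(DomainMotionError):
    """Degenerate geometry: zero-length vectors, coincident points, collinear sets."""


class DimensionError(DomainMotionError):
    """Mismatched lengths or shapes between paired inputs."""


class EmptyInputError(DomainMotionError):
    """An operation requiring at least one value received none."""


class RadiusTableError(DomainMotionError):
    """An element has no van der Waals radius in the active radius table."""


class FitError(DomainMotionError):
    """A nonlinear fit failed to converge or produced inadmissible parameters."""


class NoTransitionError(FitError):
    """A melt curve shows no detectable unfolding transition."""


class CycleError(DomainMotionError):
    """Four variants do not form a closed double-mutant cycle."""


class StatisticsError(DomainMotionError):
    """Degenerate statistical input (group too small, zero variance, ...)."""


class SpecError(DomainMotionError):
    """A synthetic-data generator spec violates its invariants."""
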