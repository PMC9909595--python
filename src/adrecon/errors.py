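"""Exception hierarchy.

Every failure mode the simulators can produce maps onto one of these classes so
callers (and the CLI) can distinguish user/configuration problems (exit 2) from
genuine errors (exit 1).
"""


class AdreconError(Exception):
    """Base class for all package errors."""


class AlphabetError(AdreconError):
    """Sequence contains characters outside the declared alphabet."""


class CoordinateError(AdreconError):
    """A span is invalid for its parent sequence."""


class TopologyError(AdreconError):
    """Operation requires the other topology (linear vs circular)."""


class ParseError(AdreconError):
    """Malformed input file."""


class DigestError(AdreconError):
    """Restriction digestion could not be carried out."""


class UncutError(DigestError):
    """No enzyme site on a circular substrate."""


class UnsupportedConfigurationError(DigestError):
    """Cut windows of two sites overlap; partial-digest semantics unsupported."""


class SelectionError(AdreconError):
    """A fragment-selection criterion matched zero or several fragments."""


class PlanningError(AdreconError):
    """Genome partition constraints cannot be satisfied."""


class DesignError(AdreconError):
    """Primer design constraint violated (uniqueness, overlap range, ...)."""


class PrimerResolutionError(DesignError):
    """A primer's annealing site could not be located uniquely on the target."""


class AmplificationError(AdreconError):
    """PCR simulation failed."""


class NoAmplificationError(AmplificationError):
    """A primer has no perfect annealing site on the template."""


class MisprimingError(AmplificationError):
    """A primer anneals at more than one site."""


class OrientationError(AmplificationError):
    """Primer pair orientation admits no product."""


class LigationError(AdreconError):
    """No compatible end joining exists."""


class AssemblyError(AdreconError):
    """Isothermal assembly failed."""


class NoSolutionError(AssemblyError):
    """Junction graph has no Hamiltonian path/cycle using all fragments."""


class AmbiguousAssemblyError(AssemblyError):
    """More than one distinct product is consistent with the overlaps."""


class GenerationError(AdreconError):
    """Synthetic-sequence constraints unsatisfiable."""


class ConfigError(AdreconError):
    """Workflow configuration invariant violated."""
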