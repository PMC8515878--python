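"""Exception hierarchy.

Everything raised on bad user input derives from :class:`PollendivError` so
callers can catch one base class at pipeline boundaries.
"""


class PollendivError(Exception):
    """Base class for all package errors."""


class TreeParseError(PollendivError):
    """Malformed Newick/NEXUS input; carries the parser's position info."""


class TreeValidationError(PollendivError):
    """Structurally valid parse that violates a tree invariant."""


class UnsupportedTopologyError(TreeValidationError):
    """Polytomies or unrooted topologies are rejected."""


class DegenerateTreeError(TreeValidationError):
    """Zero-depth or otherwise unusable tree."""


class InputError(PollendivError):
    """Inconsistent or illegal arguments to an operation."""


class EmptyProfileError(InputError):
    """All pollen types filtered out of a sample or species profile."""


class LikelihoodError(PollendivError):
    """Non-finite likelihood; carries the offending parameter vector."""

    def __init__(self, message, params=None):
        super().__init__(message)
        self.params = params


class IntegrationError(PollendivError):
    """Branch ODE integration failed at the requested tolerance."""


class FitFailureError(PollendivError):
    """Every optimisation start produced a non-finite likelihood."""


class InfeasibleSamplingError(InputError):
    """Requested unsampled-state composition impossible for the replicate."""


class SimulationAbortError(PollendivError):
    """Survival probability too low: too many rejected simulation attempts."""
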