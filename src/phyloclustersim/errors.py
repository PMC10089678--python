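"""Exception hierarchy for phyloclustersim."""


class PhyloClusterSimError(Exception):
    """Base class for all package errors."""


class ParameterError(PhyloClusterSimError, ValueError):
    """An input parameter violates its documented precondition."""


class NewickParseError(PhyloClusterSimError, ValueError):
    """A Newick string is malformed (unbalanced parentheses, empty clade,
    duplicate or missing leaf label); the message names the offending
    position or token."""


class NewickWriteError(PhyloClusterSimError, ValueError):
    """A tree cannot be serialized (e.g. a leaf without a label, or a label
    containing Newick metacharacters)."""


class GenerationError(PhyloClusterSimError, RuntimeError):
    """Cluster assembly exhausted its candidate / species-tree budget.

    Attributes carry the generation counters so callers can diagnose how
    close the run came to the requested overlap band.
    """

    def __init__(self, message, *, candidates_generated=0, rejected=0,
                 restarts=0, nearest_mean=None):
        super().__init__(message)
        self.candidates_generated = candidates_generated
        self.rejected = rejected
        self.restarts = restarts
        self.nearest_mean = nearest_mean
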