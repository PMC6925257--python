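"""Exception types shared across satdyn."""


class SatdynError(Exception):
    """Base class for all satdyn errors."""


class InvalidStateError(SatdynError):
    """A cell state or model violates an invariant (e.g. negative counts)."""


class ReplicationImpossibleError(SatdynError):
    """The cell holds no autonomous plasmid, so nothing can replicate.

    The cell is left unchanged; the caller decides the cell's fate.
    """


class InvalidCallError(SatdynError):
    """An operation was called out of order (e.g. segregating an odd pool)."""


class UndefinedResultError(SatdynError):
    """A quantity is mathematically undefined for the given inputs."""


class NoEquilibriumError(SatdynError):
    """Background-fitness tuning found no stable point in the search bracket."""


class ExtinctionError(SatdynError):
    """The focal population went extinct before the requested measurement."""

    def __init__(self, message, trajectory=None):
        super().__init__(message)
        self.trajectory = trajectory


class LayoutError(SatdynError):
    """A synthetic plasmid layout request is infeasible or overlapping."""


class InputFormatError(SatdynError):
    """An input file could not be interpreted (exit code 2 at the CLI)."""
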