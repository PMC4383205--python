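"""Exception hierarchy shared across the package."""


class RdcensError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RdcensError):
    """A file could not be parsed (carries a line number where known)."""


class TopologyError(RdcensError):
    """Conformations that should share a topology do not."""


class TableValidationError(RdcensError):
    """A tabular input violates its invariants (duplicates, bad sigma, ...)."""


class ConfigError(RdcensError):
    """A run configuration is missing a key or contains an unknown one."""


class SelectionError(RdcensError):
    """An atom/residue selection cannot be resolved in a topology."""


class MappingError(RdcensError):
    """An experimental restraint row has no calculated counterpart."""


class ConditioningError(RdcensError):
    """A linear inverse problem is rank-deficient or ill-conditioned."""


class ResolutionError(RdcensError):
    """An orientation grid is too coarse for a reliable average."""


class ScheduleError(RdcensError):
    """An annealing/collection schedule is arithmetically inconsistent."""


class BranchError(RdcensError):
    """An intensity ratio falls outside the principal extraction branch."""


class UndefinedQError(RdcensError):
    """Q factor requested against an all-zero experimental set."""
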