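"""Exception hierarchy.

Validation errors (bad inputs, broken invariants) are distinguished from
computation errors so the CLI can map them to distinct exit codes
(2 for validation, 3 for computation).
"""


class ConnRelError(Exception):
    """Base class for all package errors."""


class ValidationError(ConnRelError):
    """Invalid input data or configuration."""


class InvalidParcellationError(ValidationError):
    """Parcellation with fewer than 2 regions."""


class ShapeError(ValidationError):
    """Matrix not square / not symmetric / wrong dimensions."""


class PartitionError(ValidationError):
    """Region missing a network or lobe label, or label sets malformed."""


class DesignError(ValidationError):
    """Crossed subject x scanner design incomplete (missing cells)."""


class IntegrityError(ValidationError):
    """Duplicate rows or inconsistent values in persisted tables."""


class ConfigError(ValidationError):
    """Simulation or run configuration violates its invariants."""


class DegenerateSignalError(ValidationError):
    """A region's time series has zero variance."""


class BatchError(ValidationError):
    """Harmonisation requires >= 2 batches with >= 2 observations each."""


class CollinearityError(ValidationError):
    """Rank-deficient design matrix in harmonisation."""


class ModelMismatchError(ValidationError):
    """Applying a fitted model to incompatible data (unseen batch, wrong edges)."""


class ComputationError(ConnRelError):
    """A pipeline stage failed during numerics."""
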