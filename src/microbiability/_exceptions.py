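"""Exception hierarchy shared across the package."""


class MicrobiabilityError(Exception):
    """Base class for package errors."""


class ParameterError(MicrobiabilityError, ValueError):
    """A parameter value is outside its valid range."""


class ConfigurationError(MicrobiabilityError, ValueError):
    """A configuration references entities that do not exist or is malformed."""


class AlignmentError(MicrobiabilityError, ValueError):
    """Sample identifiers do not line up across inputs."""


class PartitionError(MicrobiabilityError, ValueError):
    """Taxon partition sets overlap or are not subsets of the table."""


class EmptyMatrixError(MicrobiabilityError, ValueError):
    """An operation produced or received a matrix with no usable rows/columns."""


class DesignError(MicrobiabilityError, ValueError):
    """Fixed-effect design matrix is singular or otherwise unusable."""


class NonIdentifiableError(MicrobiabilityError, RuntimeError):
    """Variance components cannot be separated (singular average-information matrix)."""


class DegenerateFitError(MicrobiabilityError, ValueError):
    """Response vector is constant or otherwise yields a degenerate model fit."""


class QCError(MicrobiabilityError, ValueError):
    """Quality control removed all samples or all markers."""


class FormatError(MicrobiabilityError, ValueError):
    """A file does not conform to the expected format."""
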