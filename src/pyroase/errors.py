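"""Exception hierarchy.

Every error raised by the pipeline derives from :class:`PyroaseError` so that
callers (and the CLI) can distinguish domain failures from programming errors.
"""


class PyroaseError(Exception):
    """Base class for all pyroase-specific errors."""


class InvalidMeasurementError(PyroaseError, ValueError):
    """A pyrosequencing read-out is unusable (0/100%, bad sum, bad material)."""


class InsufficientControlError(PyroaseError, ValueError):
    """No heterozygous gDNA controls available to estimate assay bias."""


class InvalidAssayError(PyroaseError, ValueError):
    """Assay-level parameter (e.g. gDNA bias) is out of its valid domain."""


class InconsistentGroupError(PyroaseError, ValueError):
    """Measurements mixed across samples, genes or materials where one group
    was required."""


class ConfigurationError(PyroaseError, ValueError):
    """Thresholds or config fields violate their constraints."""


class InsufficientSampleError(PyroaseError, ValueError):
    """Fewer than two observations in a group entering a t-test."""


class DegenerateVarianceError(PyroaseError, ValueError):
    """Both groups have zero variance; the t statistic is undefined."""


class UnphasedRecordError(PyroaseError, ValueError):
    """A candidate-SNP heterozygote entered the association test without
    known phase."""


class EmptyGroupError(PyroaseError, ValueError):
    """An operation that needs at least one record received none."""


class UnknownSiteError(PyroaseError, ValueError):
    """A methylation record sits at a position not in the island config."""


class InsufficientGroupError(PyroaseError, ValueError):
    """One of the methylation comparison groups is empty."""


class CannotAnchorError(PyroaseError, ValueError):
    """Summary table requested without a gDNA anchor group."""


class ManifestError(PyroaseError, ValueError):
    """Simulation grid contains duplicate cell identifiers."""
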