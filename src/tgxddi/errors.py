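"""Exception hierarchy for the tgxddi pipeline.

Exit-code mapping used by the CLI: configuration problems exit 2,
data problems exit 3.
"""


class TgxddiError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(TgxddiError):
    """A configuration value violates its contract."""


class DataError(TgxddiError):
    """Input data violates a structural contract."""


class UndefinedMetricError(DataError):
    """A QC metric is undefined for the given vector (e.g. all-zero counts)."""


class InsufficientSamplesError(DataError):
    """Too few samples for the requested statistic."""


class NoReferenceProbeError(DataError):
    """No probe has positive counts in every sample (size factors undefined)."""


class MissingGeneError(DataError):
    """A requested gene has no mapped probe in the count matrix."""


class PairingError(DataError):
    """A treated sample has no resolvable matched vehicle control."""


class AlignmentError(DataError):
    """Query gene set does not match the fitted model's gene set."""


class DegenerateDispersionError(DataError):
    """All pooled within-class SDs are zero and the fudge constant is zero."""


class DegenerateSampleError(DataError):
    """A sample or group has zero variance where variability is required."""


class StratifiedFoldingError(DataError):
    """A cross-validation fold lost one of the classes."""
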