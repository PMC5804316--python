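"""Exception hierarchy for the net-block evaluation pipeline.

All errors derive from :class:`BnetBenchError` so callers can catch the
package's failures in one clause; the subclasses distinguish malformed
files, invalid values, out-of-domain numerics, degenerate label vectors
and inconsistent run configurations.
"""


class BnetBenchError(Exception):
    """Base class for all package errors."""


class FormatError(BnetBenchError):
    """A file or table does not match an expected schema."""


class ValidationError(BnetBenchError):
    """A value violates a data invariant (e.g. non-positive IC50)."""


class DomainError(BnetBenchError):
    """A numeric argument is outside the mathematical domain of an operation."""


class DegenerateLabelsError(BnetBenchError):
    """A label vector contains a single class where both are required."""


class ConfigurationError(BnetBenchError):
    """A run configuration is internally inconsistent."""
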