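"""Exception hierarchy shared across the pipeline."""


class MyotuneError(Exception):
    """Base class for all package errors."""


class ConfigError(MyotuneError, ValueError):
    """Invalid configuration (bad bounds, fractions not summing to 1, ...)."""


class DataError(MyotuneError, ValueError):
    """Inconsistent or unusable data (length mismatch, empty training set)."""


class ConsistencyError(MyotuneError, ValueError):
    """Objects that should agree (channel counts, class counts) do not."""


class AllRestError(DataError):
    """A session contains no contraction-labelled samples."""


class DivergenceError(MyotuneError, RuntimeError):
    """Training produced a non-finite loss; names the offending config."""


class SessionFormatError(MyotuneError, ValueError):
    """A session file could not be parsed; names the offending line."""


class UnsupportedLayoutError(MyotuneError, ValueError):
    """An external dataset directory does not match any known layout."""


class GPConditioningError(MyotuneError, RuntimeError):
    """GP covariance stayed non-positive-definite after jitter escalation."""
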