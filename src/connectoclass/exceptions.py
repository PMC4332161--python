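"""Package-specific error types.

Degenerate inputs raise rather than silently producing empty graphs or NaN
statistics, so that cohort-level pipelines can record *which* subject or test
was undefined instead of propagating garbage.
"""


class ConnectoclassError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ConnectoclassError, ValueError):
    """A configuration field is invalid; the message names the field."""


class DegenerateMatrixError(ConnectoclassError, ValueError):
    """A connectivity matrix admits no valid transformation (e.g. constant
    off-diagonal, so no min-max scale exists)."""


class UndefinedMetricError(ConnectoclassError, ValueError):
    """A graph metric is undefined for this graph (e.g. assortativity on a
    regular graph, transitivity with no connected triplets)."""


class UndefinedStatisticError(ConnectoclassError, ValueError):
    """A statistic is undefined for this sample (e.g. zero pooled variance)."""
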