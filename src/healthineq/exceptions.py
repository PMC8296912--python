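"""Exception hierarchy for healthineq."""


class HealthineqError(Exception):
    """Base class for all healthineq errors."""


class ConfigurationError(HealthineqError):
    """A configuration value (column map, threshold, schedule...) is invalid."""


class EmptyDataError(HealthineqError):
    """No usable rows remain after validation / listwise deletion."""


class UndefinedIndexError(HealthineqError):
    """A concentration index is undefined (e.g. mean outcome is zero)."""


class ZeroMeanCovariateError(HealthineqError):
    """Covariate concentration index undefined because the covariate mean is 0."""


class DegenerateVarianceError(HealthineqError):
    """A standard error is exactly zero where a nonzero one is required."""


class ClusterError(HealthineqError):
    """Cluster-robust variance requested but the cluster structure is degenerate."""
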