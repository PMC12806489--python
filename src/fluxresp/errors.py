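"""Exception hierarchy shared across the pipeline stages."""


class FluxRespError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FluxRespError):
    """A config file or column mapping is invalid (missing column, bad YAML)."""


class InputError(FluxRespError):
    """An input file or array violates a precondition (bad timestamp, all-missing)."""


class EmptySeriesError(FluxRespError):
    """No records survive a filtering stage; the site is skipped downstream."""


class CurveFitError(FluxRespError):
    """Too few boundary points to fit the response-curve smooth."""


class SampleSizeError(FluxRespError):
    """Not enough usable records for a model fit (e.g. the random forest)."""


class CollinearityError(FluxRespError):
    """Perfectly collinear predictors; names the offending pair."""


class UndefinedStatisticError(FluxRespError):
    """A statistic is undefined for the given input (constant column, zero variance)."""


class InfeasibleConfoundError(FluxRespError):
    """Requested SM-confounder correlation is unreachable for the given marginals."""
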