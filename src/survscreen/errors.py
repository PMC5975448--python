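"""Exception hierarchy for survscreen."""


class SurvScreenError(Exception):
    """Base class for all survscreen errors."""


class ValidationError(SurvScreenError):
    """Input table or array violates the dataset contract."""


class DegenerateDataError(SurvScreenError):
    """Data carry no usable signal (e.g. zero observed events)."""


class NonIdentifiableError(SurvScreenError):
    """A Cox fit has zero information (e.g. a constant covariate)."""


class UnusableFitError(SurvScreenError):
    """An operation required a converged fit but got a failed one."""


class InvalidConfigError(SurvScreenError):
    """A configuration value is outside its admissible range."""


class DegenerateStratificationError(SurvScreenError):
    """Risk-score stratification produced an empty group."""


class UndefinedStatisticError(SurvScreenError):
    """A test statistic is undefined on these data (zero variance or no pairs)."""
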