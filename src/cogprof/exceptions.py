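"""Exception hierarchy for cogprof."""


class CogprofError(Exception):
    """Base class for all package-specific errors."""


class NormativeLookupError(CogprofError, KeyError):
    """No normative entry exists for a (test_id, score_id) pair."""


class PercentileDomainError(CogprofError, ValueError):
    """A percentile fell outside [0, 100]."""


class UnmappedScoreError(CogprofError, KeyError):
    """A score in the data has no domain assignment in the map."""


class DegenerateDataError(CogprofError, ValueError):
    """Input matrix unsuitable for factor extraction (constant/singular)."""


class UnevaluableDomainError(CogprofError, ValueError):
    """A domain has no (or too few) observed scores to classify."""


class DegenerateTableError(CogprofError, ValueError):
    """A contingency table has an empty row or column."""


class UndefinedCorrelationError(CogprofError, ValueError):
    """Correlation undefined (zero variance or too few pairs)."""


class ConfigError(CogprofError, ValueError):
    """Invalid configuration; message lists the offending fields."""
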