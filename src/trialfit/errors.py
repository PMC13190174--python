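"""Exception hierarchy.  Everything raised on purpose derives from TrialfitError."""


class TrialfitError(Exception):
    """Base class for all package errors."""


class InvalidValueError(TrialfitError, ValueError):
    """A numeric demographic value violates its domain (negative age, ...)."""


class UnmappedCategoryError(TrialfitError, KeyError):
    """An ethnicity label is not covered by the mapping and no fallback is set."""

    def __init__(self, label: str):
        self.label = label
        super().__init__(
            f"ethnicity label {label!r} is not covered by the mapping and no "
            "fallback group is configured"
        )


class EmptyCohortError(TrialfitError, ValueError):
    """An operation received an empty patient table."""


class NoValidDataError(TrialfitError, ValueError):
    """Every assignment for a feature is missing; no distribution can be built."""

    def __init__(self, feature: str):
        self.feature = feature
        super().__init__(f"no valid (non-missing) data for feature {feature!r}")


class ShapeError(TrialfitError, ValueError):
    """Probability vectors or category universes do not line up."""


class ConfigError(TrialfitError, ValueError):
    """A weight or simulation configuration violates its invariants."""


class IncompleteScoresError(TrialfitError, ValueError):
    """A weighted feature has no score and renormalisation was not requested."""


class SamplingError(TrialfitError, ValueError):
    """A cohort draw is impossible (size exceeds the pool, ...)."""


class UndefinedCorrelationError(TrialfitError, ValueError):
    """Correlation of a constant vector is undefined."""


class SchemaError(TrialfitError, ValueError):
    """An input table is missing a required column."""
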