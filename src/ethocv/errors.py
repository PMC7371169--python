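"""Exception hierarchy for input validation failures.

Every precondition violation raises a subclass of :class:`ValidationError`
so callers can catch one type, while tests can assert on the specific one.
"""


class ValidationError(ValueError):
    """An input violated a documented precondition."""


class ChannelCountError(ValidationError):
    """A recording file did not contain exactly the expected channels."""


class NonMonotoneTimeError(ValidationError):
    """Timestamps in a recording are not strictly increasing."""


class RateMismatchError(ValidationError):
    """Inferred sampling rate disagrees with the declared rate."""


class UnknownBehaviourError(ValidationError):
    """A behaviour label outside the configured ethogram was encountered."""


class OverlapError(ValidationError):
    """Two label intervals overlap."""


class EmptyDatasetError(ValidationError):
    """An operation produced or received a dataset with no rows."""


class FeatureMismatchError(ValidationError):
    """Feature names of a dataset do not match the model's training features."""
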