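"""Exception hierarchy. All package errors derive from McdaError."""


class McdaError(Exception):
    """Base class for all errors raised by tendermcda."""


class FrameworkSchemaError(McdaError):
    """A framework config file does not match the documented schema."""


class FrameworkInvalidError(McdaError):
    """A framework failed validation where a valid one is required."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__(
            "invalid framework: " + "; ".join(str(v) for v in self.violations)
        )


class VoteError(McdaError):
    """A voting round is malformed (empty, off-grid value, unknown id...)."""


class ElicitationError(McdaError):
    """The vote record cannot produce a complete weighted framework."""


class UnknownCategoryError(McdaError):
    """A selected performance-category label does not exist on the criterion."""


class SelectionError(McdaError):
    """A product's performance selections do not cover the framework."""


class PriceError(McdaError):
    """A bid price is inconsistent with the price context (e.g. below p_min)."""
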