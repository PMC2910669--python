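"""Exception hierarchy for betasift."""


class BetasiftError(Exception):
    """Base class for all betasift errors."""


class ParseError(BetasiftError):
    """An on-disk container could not be parsed; the message names the field."""


class EpochValidationError(BetasiftError):
    """An epoch violates its invariants (shape, labels, finiteness)."""


class ConfigurationError(BetasiftError):
    """A parameter or label configuration is invalid."""


class BoundsError(BetasiftError):
    """A time window falls outside the epoch's span."""


class DegenerateInputError(BetasiftError):
    """A correlation was requested on constant (zero-variance) input."""


class SelectionError(BetasiftError):
    """IMF selection failed; the trial should be flagged unusable."""


class NoBandError(BetasiftError):
    """No supra-threshold frequency band was found where one is required."""


class InsufficientExtremaError(BetasiftError):
    """Too few extrema to build spline envelopes; sifting must stop."""
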