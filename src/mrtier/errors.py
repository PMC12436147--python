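"""Exception hierarchy for validation and contract errors."""


class MRTierError(Exception):
    """Base class for all package errors."""


class FormatError(MRTierError):
    """A required column or field is missing or malformed."""


class EmptyDatasetError(MRTierError):
    """An input table contained no usable rows."""


class EmptyOverlapError(MRTierError):
    """Exposure and outcome share no variants after matching."""


class UndefinedRatioError(MRTierError):
    """Wald ratio requested with a zero exposure effect."""


class InsufficientInstrumentsError(MRTierError):
    """An estimator was called with fewer instruments than it needs."""


class IncompleteEvidenceError(MRTierError):
    """Tier assignment requested with a missing stage output."""
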