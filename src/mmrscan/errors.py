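"""Exception hierarchy for mmrscan."""


class MMRScanError(Exception):
    """Base class for all mmrscan errors."""


class UndefinedVAFError(MMRScanError):
    """VAF requested for a variant with zero total tumor coverage."""


class PurityError(MMRScanError):
    """Tumor purity missing or non-positive; zygosity cannot be called."""


class MappingError(MMRScanError):
    """A variant position does not fall inside its transcript's exons."""


class ConfigurationError(MMRScanError):
    """Required configuration (e.g. a transcript model) is missing."""


class ValidationError(MMRScanError):
    """An input record violates a declared invariant."""


class DegenerateInputError(MMRScanError):
    """A statistical routine received an input on which its test is undefined
    (zero margin contingency table, single survival group, no events)."""
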