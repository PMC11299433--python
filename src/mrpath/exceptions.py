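"""Exception hierarchy for mrpath.

Every error a caller may want to catch and recover from (e.g. a trait with no
genome-wide-significant instruments, which the pipeline handles by relaxing the
threshold or skipping the trait) has its own type.
"""


class MRPathError(Exception):
    """Base class for all mrpath errors."""


class ConfigurationError(MRPathError):
    """An invalid configuration value; the message names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class DataError(MRPathError):
    """Malformed input data (schema violation, duplicated SNP ids, ...)."""


class NoInstrumentsError(MRPathError):
    """Instrument selection returned an empty set for a trait.

    Carries the trait name so a caller may relax the p-value threshold,
    mirroring the fallback used for traits with no genome-wide-significant
    hits.
    """

    def __init__(self, trait: str, message: str = ""):
        self.trait = trait
        super().__init__(message or f"no instruments selected for trait {trait!r}")


class EstimationError(MRPathError):
    """An estimator's preconditions are not met (too few SNPs, etc.)."""


class PressoNotApplicableError(EstimationError):
    """MR-PRESSO requires at least 4 instruments."""
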