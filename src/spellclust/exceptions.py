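"""Exception hierarchy for spellclust."""


class SpellclustError(Exception):
    """Base class for all spellclust errors."""


class CohortFormatError(SpellclustError):
    """A cohort CSV cell or header could not be parsed."""


class ValidationError(SpellclustError):
    """An input violated a structural contract (duplicate ids, shape mismatch, ...)."""


class CoverageError(SpellclustError):
    """A sequence assigner did not cover the full sequence space."""


class NoComparableVariablesError(SpellclustError):
    """A pair of subjects shares no observed variable, so no distance is defined."""
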