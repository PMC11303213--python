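"""Exception hierarchy.

Every error raised by this package derives from :class:`CarrierPrevError`,
so callers (and the CLI) can catch one type and report the failing stage.
"""


class CarrierPrevError(Exception):
    """Base class for all carrierprev errors."""


class VcfParseError(CarrierPrevError):
    """A VCF data line could not be parsed; the message names the line number."""


class VcfStructureError(CarrierPrevError):
    """VCF structure is inconsistent (e.g. sample count differs between header and records)."""


class PanelParseError(CarrierPrevError):
    """A sample-panel line does not have the expected sample/pop/super_pop fields."""


class PanelConflictError(CarrierPrevError):
    """The same sample appears with two different population assignments."""


class EmptyPanelError(CarrierPrevError):
    """The panel file contains no sample entries."""


class InvalidVariantError(CarrierPrevError):
    """A variant key violates its invariants (e.g. ref == alt after trimming)."""


class VocabularyError(CarrierPrevError):
    """A classification token is outside the closed vocabulary."""


class UnassignedSamplesError(CarrierPrevError):
    """Cohort samples are missing from the sample panel; message lists them."""


class FrequencyRangeError(CarrierPrevError):
    """An allele frequency is outside [0, 1] after interpretation."""


class UndefinedFrequencyError(CarrierPrevError):
    """Allele number is zero, so the frequency is undefined."""


class UsageError(CarrierPrevError):
    """An operation was called with inconsistent arguments (caller bug)."""


class FeasibilityError(CarrierPrevError):
    """A fixture specification cannot be satisfied (e.g. more carriers than samples)."""
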