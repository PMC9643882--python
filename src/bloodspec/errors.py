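"""Exception hierarchy for the bloodspec pipeline."""


class BloodspecError(Exception):
    """Base class for all package-specific errors."""


class InvalidCompositionError(BloodspecError):
    """Mass fractions are outside [0, 1] or do not sum to one."""


class DegenerateSpectrumError(BloodspecError):
    """A spectrum cannot be normalized (zero variance, vanishing MSC slope)."""


class NotFittedError(BloodspecError):
    """A fit-dependent transform was applied before fitting."""


class EmptySelectionError(BloodspecError):
    """Variable selection terminated without selecting any variable."""


class SpectraIOError(BloodspecError):
    """Malformed spectra/metadata files (id mismatches, non-numeric cells...)."""
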