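"""Exception and warning types shared across the pipeline."""


class ParameterError(ValueError):
    """A configuration or generator parameter is out of its valid range."""


class MeasurementError(ValueError):
    """A densitometric measurement cannot be computed (bad pixels, empty mask)."""


class NormalizationError(ValueError):
    """A specimen cannot be normalized to c-units (no reference cells)."""


class StateError(RuntimeError):
    """An operation was called on a specimen in the wrong state (e.g. unnormalized)."""


class CohortValidationError(ValueError):
    """A cohort table violates its invariants (missing outcomes, bad categories)."""


class ModelError(ValueError):
    """A regression design is unusable (rank deficient, empty)."""


class FixtureIntegrityError(RuntimeError):
    """The packaged study fixture does not match its recorded totals/checksum."""

    def __init__(self, message: str, expected=None, found=None):
        super().__init__(message)
        self.expected = expected
        self.found = found


class SaturationWarning(UserWarning):
    """Pixels brighter than the background were clamped to optical density 0."""
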