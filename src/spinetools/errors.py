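"""Exception types shared across the pipeline stages."""


class SpinetoolsError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SpinetoolsError, ValueError):
    """A specification or configuration value violates its contract."""


class SizingError(ValidationError):
    """A phantom volume is too small for the requested content."""


class PlacementError(SpinetoolsError):
    """Synthetic objects could not be placed without overlap."""


class SeedError(SpinetoolsError, ValueError):
    """A manual seed selection does not intersect the mask."""


class RefinementError(SpinetoolsError, ValueError):
    """A mask edit would leave an empty object."""


class CensusError(SpinetoolsError, ValueError):
    """The spine census has an empty denominator."""


class NormalizationError(SpinetoolsError, ValueError):
    """Internal-standard normalization is impossible for a sample."""


class ReferenceGeneError(SpinetoolsError, ValueError):
    """The reference gene is missing or has zero variance."""


class SchemaError(SpinetoolsError, ValueError):
    """An input table violates the expected schema."""
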