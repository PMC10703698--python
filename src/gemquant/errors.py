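"""Exception hierarchy.

Every error raised on bad scientific input derives from :class:`GemQuantError`
so pipeline drivers can catch one type and report the failing stage.
"""


class GemQuantError(ValueError):
    """Base class for all gemquant errors."""


class GeometryError(GemQuantError):
    """Masks/volumes do not intersect or geometries are incompatible."""


class PlacementError(GemQuantError):
    """A requested particle count could not be placed within the retry budget."""


class ResolutionError(GemQuantError):
    """A physical radius is too small for the voxel grid to resolve."""


class NormalizationError(GemQuantError):
    """Normalization is undefined (zero variance, non-positive prebleach mean...)."""


class InputError(GemQuantError):
    """Invalid or empty input where the operation demands data."""


class SchemaError(GemQuantError):
    """A table is missing required columns or contains malformed rows."""


class LedgerError(GemQuantError):
    """A curation ledger is internally inconsistent."""


class IdentifiabilityError(GemQuantError):
    """A model fit is degenerate (non-recovering trace, flat data)."""


class ConfigError(GemQuantError):
    """A configuration value violates its invariants or has unknown keys."""
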