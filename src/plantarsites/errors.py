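"""Exception hierarchy for the plantar testing-site pipeline.

Every failure mode that a caller may want to catch separately gets its own
class; all inherit from :class:`PlantarSitesError` so that the CLI can map
any pipeline failure to a nonzero exit code in one place.
"""


class PlantarSitesError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(PlantarSitesError):
    """Invalid or unknown configuration key/value."""


# --- annotation I/O -------------------------------------------------------

class AmbiguousColor(PlantarSitesError):
    """A pixel is within the matching tolerance of two or more palette colors."""


class UnknownColor(PlantarSitesError):
    """Strict decoding found a non-background pixel matching no palette color."""


# --- segmentation ---------------------------------------------------------

class FeetNotFound(PlantarSitesError):
    """Fewer than two qualifying foot regions were segmented from the scene.

    This is the run-level failure the screening workflow must surface for
    manual review, not silently ignore.
    """


class DegenerateRegion(PlantarSitesError):
    """A region is too small (or too thin) to support the requested measurement."""


class OutOfBounds(PlantarSitesError):
    """A remapped point falls outside the scene raster."""


class EmptyToesView(PlantarSitesError):
    """The toes sub-view of a normalized foot contains no foreground."""


class NoPeakFound(PlantarSitesError):
    """The upper contour profile has no prominent local minimum (no toe tip)."""


class RowMissesFoot(PlantarSitesError):
    """A horizontal scan row does not intersect the foot mask."""


class LineMissesFoot(PlantarSitesError):
    """A guideline does not intersect the foot mask."""


# --- evaluation -----------------------------------------------------------

class ShapeMismatch(PlantarSitesError):
    """Two masks being compared do not share the same dimensions."""


class ZeroFeet(PlantarSitesError):
    """Feet-detection accuracy requested with a zero denominator."""


class EmptyList(PlantarSitesError):
    """An aggregate metric was requested over an empty collection."""


class NoPairs(PlantarSitesError):
    """No (estimate, reference) pairs could be formed for evaluation."""


# --- synthetic fixtures ---------------------------------------------------

class InvalidParams(PlantarSitesError):
    """Synthetic foot geometry parameters violate their invariants."""


class LayoutConflict(PlantarSitesError):
    """Two feet (or a foot and a marker) overlap in a rendered scene."""


class UnknownPreset(PlantarSitesError):
    """Fixture suite requested with an unrecognized preset name."""
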