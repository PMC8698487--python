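"""Exception hierarchy shared across the package."""


class MvcError(Exception):
    """Base class for all package-specific errors."""


class MeshFormatError(MvcError):
    """A mesh file violates its declared format (bad indices, non-triangle faces...)."""


class MeshInvariantError(MvcError):
    """An in-memory mesh violates the triangle-mesh invariants."""


class ManifestError(MvcError):
    """A cohort manifest is inconsistent (duplicate IDs, side conflicts...)."""


class AlignmentError(MvcError):
    """Coarse alignment failed (degenerate covariance, rank-deficient shape)."""


class FitError(MvcError):
    """Closed-form rigid fit is underdetermined (too few or collinear points)."""


class RegistrationError(MvcError):
    """Trimmed-ICP registration could not proceed (degenerate retained set)."""


class FragmentError(MvcError):
    """Fragment cropping produced an unusable mesh."""


class ConfigurationError(MvcError):
    """A run/cohort configuration is invalid."""


class StatisticsError(MvcError):
    """ROC statistics are undefined for the given input (single class...)."""
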