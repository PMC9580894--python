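"""Exception hierarchy shared across the package.

Every user-facing failure derives from :class:`GlyphstackError` so the CLI can
surface a diagnostic message instead of a bare traceback.
"""


class GlyphstackError(Exception):
    """Base class for all glyphstack errors."""


class InvalidShapeError(GlyphstackError):
    """A shape definition cannot produce a valid closed path."""


class InvalidDimensionError(GlyphstackError):
    """A shape dimension is non-positive."""


class DomainError(GlyphstackError):
    """A value lies outside its documented domain (e.g. v outside [0, 1])."""


class ConfigurationError(GlyphstackError):
    """An unknown palette, fixture kind, or other configuration value."""


class TableLoadError(GlyphstackError):
    """A delimited table could not be read or parsed."""


class NormalizationError(GlyphstackError):
    """Normalization preconditions violated (empty column, unknown group member)."""


class TemplateValidationError(GlyphstackError):
    """Template document failed schema or semantic validation.

    Carries *all* failures, not just the first, as ``errors``.
    """

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("template validation failed:\n" + "\n".join(f"  - {e}" for e in self.errors))


class RenderError(GlyphstackError):
    """Rendering failed (missing variable, page out of range, bad layout)."""
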