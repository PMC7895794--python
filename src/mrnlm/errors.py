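"""Typed exceptions shared across the package.

All domain errors derive from :class:`MRNLMError` so callers (and the CLI)
can distinguish configuration, geometry, shape and numerical problems from
ordinary Python failures.
"""


class MRNLMError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(MRNLMError, ValueError):
    """A filter/generator parameter is outside its valid domain."""


class ShapeError(MRNLMError, ValueError):
    """Volumes, masks or grids do not have compatible shapes/spacings."""


class GeometryError(MRNLMError, ValueError):
    """Phantom geometry is inconsistent (overlapping/out-of-bounds solids)."""


class ConfigError(MRNLMError, ValueError):
    """A configuration file or method label is invalid."""


class UndefinedMetricError(MRNLMError, ArithmeticError):
    """A metric denominator is zero; the statistic is undefined rather than infinite."""
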