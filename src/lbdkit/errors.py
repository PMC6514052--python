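"""Exception hierarchy.

All lbdkit errors derive from :class:`LbdkitError` so callers can catch the
package's failures with one clause; most also derive from ``ValueError`` to
stay unsurprising in scripts.
"""


class LbdkitError(Exception):
    """Base class for all lbdkit errors."""


class ParseError(LbdkitError, ValueError):
    """A file or expression could not be parsed; the message names the position."""


class StructureError(LbdkitError, ValueError):
    """A structure or trajectory violates an invariant (e.g. atom-count mismatch)."""


class SelectionError(LbdkitError, ValueError):
    """A selection did not resolve to the required atoms."""


class ConfigurationError(LbdkitError, ValueError):
    """Invalid parameter combination (bad cutoff, PBC without a box, ...)."""


class InsufficientDataError(LbdkitError, ValueError):
    """Too few frames/points for the requested analysis."""


class DegenerateGeometryError(LbdkitError, ValueError):
    """Geometry is degenerate (fewer than 3 points, or all collinear)."""


class GenerationError(LbdkitError, ValueError):
    """A synthetic-data request cannot be satisfied."""
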