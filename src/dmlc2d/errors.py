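"""Exception hierarchy for dmlc2d.

All errors derive from :class:`Dmlc2dError` so callers can catch the
package's failures with a single ``except`` clause; each subclass also
derives from the matching builtin (``ValueError`` for bad data,
``RuntimeError`` for pipeline-state problems) so generic handling keeps
working.
"""


class Dmlc2dError(Exception):
    """Base class for all dmlc2d errors."""


class FluenceFormatError(Dmlc2dError, ValueError):
    """Malformed fluence-grid file: missing header field, bad shape, ..."""


class ValidationError(Dmlc2dError, ValueError):
    """Invalid in-memory data (negative fluence, non-finite values, ...)."""


class ResolutionError(Dmlc2dError, ValueError):
    """Fluence row height incompatible with leaf widths; upsample first."""


class DegenerateInputError(Dmlc2dError, ValueError):
    """Operation undefined on this input (all-zero map, zero planned area)."""


class PlanError(Dmlc2dError, ValueError):
    """Sector plan inconsistent with the fluence grid it is applied to."""
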