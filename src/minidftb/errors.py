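"""Exception taxonomy.

Every user-facing failure mode carries a stable ``code`` string so the CLI can
report machine-readable errors.
"""


class MiniDFTBError(Exception):
    code = "error"


class ParseError(MiniDFTBError):
    """Malformed input file (names the offending line where possible)."""

    code = "parse"


class LayoutError(MiniDFTBError):
    """File layout inconsistent with the declared element pair."""

    code = "layout"


class TableRangeError(MiniDFTBError):
    """Distance outside the tabulated Slater-Koster range; no extrapolation."""

    code = "range"


class ConfigurationError(MiniDFTBError):
    """Missing or inconsistent parameters / configuration."""

    code = "config"


class CapabilityError(MiniDFTBError):
    """Requested feature outside the supported model space (e.g. l > 1)."""

    code = "capability"


class DomainError(MiniDFTBError):
    """Parameter outside its mathematical domain (e.g. U <= 0)."""

    code = "domain"


class CapacityError(MiniDFTBError):
    """Electron count exceeds basis capacity."""

    code = "capacity"


class NumericError(MiniDFTBError):
    """Linear-algebra failure (e.g. non-positive-definite overlap)."""

    code = "numeric"


class GeometryError(MiniDFTBError):
    """Invalid geometry (coincident atoms, empty molecule, ...)."""

    code = "geometry"


class ConsistencyError(MiniDFTBError):
    """Internally inconsistent state handed to an operation."""

    code = "consistency"


class UnsupportedFeatureError(MiniDFTBError):
    """Declared limitation hit (e.g. periodic gen geometry)."""

    code = "unsupported"
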