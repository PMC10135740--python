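"""Exception hierarchy.

Every error raised by the library derives from :class:`TrrdfError` and
carries a short category name used by the command-line interface to report
failures in a machine-greppable way.
"""


class TrrdfError(Exception):
    """Base class for all library errors."""

    category = "error"


class FormatError(TrrdfError):
    """A trajectory or topology file could not be parsed."""

    category = "format"


class TopologyError(TrrdfError):
    """Topology metadata is inconsistent (e.g. atom-count mismatch)."""

    category = "topology"


class CellError(TrrdfError):
    """Unit-cell information is missing, singular or invalid."""

    category = "cell"


class SelectionError(TrrdfError):
    """A selection expression could not be parsed."""

    category = "selection"


class EmptySelectionError(SelectionError):
    """A syntactically valid selection matched zero atoms."""

    category = "selection"


class PBCRangeError(TrrdfError):
    """Requested histogram range exceeds the minimum-image validity radius."""

    category = "pbc-range"


class MappingError(TrrdfError):
    """Cluster labels and trajectory windows have no temporal overlap."""

    category = "mapping"
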