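"""Exception hierarchy for genectx.

Every user-facing failure raises a subclass of :class:`GenectxError` with a
message that names the offending object (gene id, neighborhood id, file line),
so the CLI can map them onto exit codes without string matching.
"""


class GenectxError(Exception):
    """Base class for all genectx errors."""


class AnchorNotFoundError(GenectxError):
    """Requested anchor gene id does not exist in the genome."""


class DuplicateGeneIdError(GenectxError):
    """A gene id occurs more than once where uniqueness is required."""


class EmptyNeighborhoodError(GenectxError):
    """An alignment was requested on an empty label vector."""


class NothingToClusterError(GenectxError):
    """Clustering was requested on an empty neighborhood set."""


class TrackLimitError(GenectxError):
    """More tracks were requested than the renderer allows."""


class FormatError(GenectxError):
    """A file does not conform to its documented dialect."""
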