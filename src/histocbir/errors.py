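"""Exception hierarchy for histocbir.

All package-specific failures derive from :class:`HistoCBIRError` so callers
can catch the whole family with one clause while the CLI maps each subtype to
an actionable message.
"""


class HistoCBIRError(Exception):
    """Base class for all histocbir errors."""


class UnknownBackboneError(HistoCBIRError, KeyError):
    """A backbone name is not present in the registry catalogue."""


class UnknownLayerError(HistoCBIRError, KeyError):
    """A layer name is not registered for the given backbone."""


class ShapeMismatchError(HistoCBIRError):
    """A backend produced a feature map whose shape contradicts the registry."""


class ConsistencyError(HistoCBIRError):
    """Heterogeneous provenance, lengths or duplicate ids where uniformity is required."""


class DegenerateVectorError(HistoCBIRError):
    """A zero-norm vector reached the cosine similarity; usually a dead layer or backend bug."""


class DimensionError(HistoCBIRError):
    """Vector lengths disagree."""


class InsufficientCandidatesError(HistoCBIRError):
    """k exceeds the number of available ranked candidates."""


class BankFormatError(HistoCBIRError):
    """A persisted feature bank is missing metadata or has an unsupported schema."""


class IncompleteGridError(HistoCBIRError):
    """A metric table is missing cells required by a selection procedure."""


class ConfigurationError(HistoCBIRError):
    """Missing or invalid configuration (channel statistics, backend choice, ...)."""
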