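"""Exception hierarchy.

Every failure mode the library signals derives from :class:`MednaError` so
callers (and the CLI) can catch one base class. Subclasses are deliberately
fine-grained: the contracts distinguish, e.g., a missing vocabulary from an
inactive code, or an occupied freezer slot from an invalid state transition.
"""


class MednaError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(MednaError):
    """A shipped or user-supplied config file is malformed."""


class DuplicateError(MednaError):
    """An insert collides with an existing record or code."""


class PermissionError_(MednaError):
    """The acting principal lacks the required grant."""


class ImmutableError(MednaError):
    """Attempt to modify a frozen (enumerated) vocabulary entry."""


class NotFoundError(MednaError):
    """A referenced record, vocabulary or code does not exist."""


class InactiveError(NotFoundError):
    """The code exists but has been deactivated (soft-deleted)."""


class ParseError(MednaError):
    """An identifier string does not match its grammar.

    ``component`` names the part of the grammar that failed
    (separator, project, region, system, sequence, year, material).
    """

    def __init__(self, message: str, component: str):
        super().__init__(message)
        self.component = component


class RangeError(MednaError):
    """A numeric field lies outside its permitted range."""


class CapacityError(MednaError):
    """An identifier scope has no remaining sequence numbers."""


class ValidationError(MednaError):
    """A record violates a domain invariant."""


class PolymorphismError(ValidationError):
    """Subtype payload does not match the declared supertype kind."""


class ConsistencyError(ValidationError):
    """Cross-record consistency violated (e.g. barcode material mismatch)."""


class DoubleBindError(ValidationError):
    """A sample barcode is already bound to another record."""


class DemultiplexConflictError(ValidationError):
    """Two libraries in one pool share an (i7, i5) index pair."""


class GeometryError(MednaError):
    """Invalid geometric input (bad coordinates, degenerate ring)."""


class UnassignedRegionError(MednaError):
    """A point falls inside no region polygon."""


class MergeError(MednaError):
    """Region-set merge failed (code collision)."""


class StateError(MednaError):
    """Inventory state machine rejects the transition."""


class OccupancyError(StateError):
    """Storage location already holds an in-storage item."""


class VolumeError(StateError):
    """Aliquot volume exceeds the stored volume."""


class ReplayError(MednaError):
    """Ledger replay hit an invalid transition.

    ``seq_no`` identifies the offending entry.
    """

    def __init__(self, message: str, seq_no: int):
        super().__init__(message)
        self.seq_no = seq_no


class LineageError(MednaError):
    """Provenance chain is broken; ``missing_hop`` names the first gap."""

    def __init__(self, message: str, missing_hop: str):
        super().__init__(message)
        self.missing_hop = missing_hop


class AmbiguityError(LineageError):
    """A FASTQ record cannot be attributed to a single extraction."""

    def __init__(self, message: str):
        super().__init__(message, missing_hop="extraction")


class IntegrityError(MednaError):
    """Referential-integrity scan or CSV import found dangling references."""
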