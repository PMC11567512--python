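"""Exception hierarchy shared across modules."""


class PrioritySimError(Exception):
    """Base class for all package errors."""


class ValidationError(PrioritySimError, ValueError):
    """A domain object violates one of its invariants.

    ``field`` names the offending field so that callers (and error messages)
    can point at the exact piece of configuration that is wrong.
    """

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class ParseError(PrioritySimError, ValueError):
    """A scenario file could not be parsed; carries file/field context."""


class UnknownTreatmentError(PrioritySimError, KeyError):
    """A treatment id was referenced that is not in the catalogue/policy."""


class CapabilityLookupError(PrioritySimError, KeyError):
    """An unknown (facility, cadre) pair was queried on a capability ledger."""
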