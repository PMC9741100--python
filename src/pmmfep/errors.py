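"""Exception hierarchy shared by all pmmfep modules."""

from __future__ import annotations


class PMMError(Exception):
    """Base class for all pmmfep errors."""


class SchemaError(PMMError):
    """A file does not conform to the documented schema."""


class InvariantError(PMMError, ValueError):
    """A domain-type invariant is violated (names the offending field/point)."""


class DegenerateGeometryError(PMMError, ValueError):
    """Coincident atoms produce a zero-length bond."""


class SingularGeometryError(PMMError, ValueError):
    """An environment particle sits inside the clash distance of an expansion center."""


class UnsupportedBoxError(PMMError, ValueError):
    """Only orthorhombic periodic boxes are supported."""


class ContractError(PMMError, ValueError):
    """An operation precondition (dimensions, symmetry) is violated."""
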