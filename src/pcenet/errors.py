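"""Exception hierarchy for pcenet.

Every stage raises a subclass of :class:`PcenetError` so pipeline code can
attach stage provenance without catching bare ``ValueError``.
"""


class PcenetError(Exception):
    """Base class for all pcenet errors."""


class ParseError(PcenetError):
    """Malformed input text (e.g. duplicate ids in an INP file)."""


class StructuralError(PcenetError):
    """Network violates a structural invariant (unknown node, disconnected)."""


class AttributeTableError(PcenetError):
    """Pipe attribute table inconsistent with the network."""


class SolverError(PcenetError):
    """Hydraulic solver failed to converge; carries the residual."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class DegenerateInputError(PcenetError):
    """Input is valid syntactically but degenerate (e.g. zero total demand)."""


class TransportError(PcenetError):
    """Contaminant transport cannot be computed on this flow solution."""


class MappingError(PcenetError):
    """A residence or sample references a node absent from the network."""


class ParameterError(PcenetError):
    """Out-of-range model or analysis parameter."""


class SmoothingError(PcenetError):
    """LOESS smoothing failed (span too small for local neighborhoods)."""


class ConfigError(PcenetError):
    """Invalid run or generator configuration."""
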