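"""Exception hierarchy.

Everything raised on purpose derives from :class:`RarehapError` so callers
(and the CLI) can distinguish engine diagnostics from genuine bugs.
"""

from __future__ import annotations


class RarehapError(Exception):
    """Base class for all errors raised by rarehap."""


class FormatError(RarehapError):
    """A file does not conform to the expected dialect (missing column, ragged rows)."""


class LegendParseError(FormatError):
    """A legend field could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class PairingError(RarehapError):
    """A legend and haplotype matrix that should be paired have mismatched row counts."""


class SchemaError(RarehapError):
    """A MAC-bin schema does not match the data it is applied to."""


class DomainError(RarehapError, ValueError):
    """An argument is outside its mathematical domain."""


class FitError(RarehapError):
    """A parameter fit is infeasible (too few points / too few informative bins)."""


class CapacityError(RarehapError):
    """More haplotype columns were requested than are available."""


class ConstraintError(RarehapError):
    """Scenario weights violate the required inequalities."""


class InfeasibleSelectionError(RarehapError):
    """A weighted selection asked for more items than have positive weight."""

    def __init__(self, message: str, shortfall: int = 0):
        self.shortfall = shortfall
        super().__init__(message)


class DegeneratePhenotypeError(RarehapError):
    """The phenotype vector is constant; no association test is defined."""


class ConfigError(RarehapError):
    """A configuration value is unusable (e.g. too few permutations/replicates)."""
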