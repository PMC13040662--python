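"""Exception hierarchy shared across the package."""


class PrsmedError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PrsmedError):
    """A file could not be parsed in the expected dialect."""


class ParameterError(PrsmedError):
    """Invalid simulation or analysis parameters."""


class HarmonizationError(PrsmedError):
    """Scoring and genotype variant sets are incompatible."""


class ScoringError(PrsmedError):
    """A score could not be computed (e.g. missing reference allele frequency)."""


class DesignError(PrsmedError):
    """Rank-deficient or otherwise invalid regression design."""


class DataError(PrsmedError):
    """Invalid data values (e.g. non-positive value at a log step)."""


class SubsetError(PrsmedError):
    """A requested cohort subset is empty or degenerate."""


class PanelError(PrsmedError):
    """An entire mediator panel failed."""
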