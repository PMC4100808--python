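"""Exception hierarchy shared across the pipeline.

The CLI maps these onto its exit-code contract: schema errors exit 2,
an empty post-QC cohort exits 3, statistical degeneracy exits 4.
"""


class MthetError(Exception):
    """Base class for all package-specific errors."""


class CoordinateError(MthetError, ValueError):
    """A position lies outside the genome or the analysed fragment."""


class SchemaError(MthetError, ValueError):
    """An input file or table violates its schema (reported with line numbers)."""


class ParameterError(MthetError, ValueError):
    """An argument or configuration value violates a precondition."""


class QCEmptyError(MthetError, RuntimeError):
    """No sample survived coverage quality control."""


class DegenerateStatisticError(MthetError, RuntimeError):
    """A statistic is undefined on the given data (e.g. zero variance)."""
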