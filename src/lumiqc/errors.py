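"""Exception hierarchy for lumiqc.

All package errors derive from :class:`LumiqcError` so callers can catch
anything raised by the pipeline with a single except clause.
"""


class LumiqcError(Exception):
    """Base class for all lumiqc errors."""


# --- plate / platemap I/O ---------------------------------------------------

class MalformedPlate(LumiqcError):
    """Plate matrix has wrong dimensions, non-numeric cells or duplicate rows."""


class DuplicateWell(LumiqcError):
    """A platemap lists the same well more than once."""


class UnknownRole(LumiqcError):
    """A platemap row carries a role outside the known vocabulary."""


class MissingConcentration(LumiqcError):
    """A sample well lacks a compound concentration."""


class LayoutOverflow(LumiqcError):
    """A requested design does not fit on a 384-well plate."""


# --- QC / normalization -----------------------------------------------------

class MissingControls(LumiqcError):
    """Fewer than two negative or positive control wells on the plate."""


class DegenerateControls(LumiqcError):
    """Control means coincide (mu_n == mu_p) or mu_n == 0; normalization undefined."""


class ZeroMean(LumiqcError):
    """Coefficient of variation requested for values with zero mean."""


# --- dose-response ----------------------------------------------------------

class InvalidParams(LumiqcError):
    """Log-logistic parameters violate their domain (e.g. inflection <= 0)."""


class FitFailure(LumiqcError):
    """Nonlinear least squares failed to produce any converged solution."""


class InvalidRange(LumiqcError):
    """Concentration range is empty, inverted, or non-positive."""


# --- screen-level analysis --------------------------------------------------

class NegativeResidual(LumiqcError):
    """Residual-signal percentage below zero passed to the colour-band rule."""


class InsufficientOverlap(LumiqcError):
    """Fewer than three shared compounds between observed and reference orders."""


class UnmatchedCells(LumiqcError):
    """Baseline and modifier conditions share no matching cells."""


class UnknownScenario(LumiqcError):
    """Requested simulation scenario preset does not exist."""
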