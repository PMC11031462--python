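"""Exception hierarchy for piolcalc."""


class PiolCalcError(Exception):
    """Base class for all piolcalc errors."""


class OpticsError(PiolCalcError):
    """Invalid paraxial operation (zero radius, focal singularity, ...)."""


class GeometryError(PiolCalcError):
    """Physically inconsistent element layout (negative gaps, overlap)."""


class DesignError(PiolCalcError):
    """A lens design cannot be completed or violates its invariants."""


class CohortError(PiolCalcError):
    """Invalid cohort specification or unusable biometry record."""


class FitError(PiolCalcError):
    """Regression fitting failed (rank deficiency, too few rows)."""
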