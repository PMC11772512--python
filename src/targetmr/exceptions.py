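"""Exception hierarchy for targetmr."""


class TargetMRError(Exception):
    """Base class for all targetmr errors."""


class FormatError(TargetMRError):
    """A file does not have the expected layout (missing columns, bad header)."""


class ValidationError(TargetMRError):
    """Record-level contents violate an invariant (se <= 0, bad p-value, ...).

    Carries the offending 1-based file line numbers when known.
    """

    def __init__(self, message, lines=None):
        super().__init__(message)
        self.lines = list(lines) if lines is not None else []


class ConfigurationError(TargetMRError):
    """Inputs are individually valid but mutually inconsistent (SNP absent
    from the LD reference, infeasible variance allocation, empty gene list)."""


class EmptyPairError(TargetMRError):
    """Exposure and outcome share no usable SNPs after harmonization."""


class UndefinedRatioError(TargetMRError):
    """A Wald/SMR ratio with zero exposure effect."""


class CollinearityError(TargetMRError):
    """Rank-deficient exposure matrix in multivariable MR."""

    def __init__(self, message, columns=None):
        super().__init__(message)
        self.columns = list(columns) if columns is not None else []


class StrengthUnavailableError(TargetMRError):
    """F/R^2 requested but allele frequency or sample size is missing."""
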