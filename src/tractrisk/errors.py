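"""Exception hierarchy shared across the pipeline."""


class TractRiskError(Exception):
    """Base class for all package-specific errors."""


class ArgumentError(TractRiskError, ValueError):
    """An argument violates a documented precondition."""


class DataError(TractRiskError, ValueError):
    """An input table is structurally invalid or inconsistent."""


class ConfigError(TractRiskError, ValueError):
    """A configuration object references unknown fields or invalid values."""


class StatisticError(TractRiskError, ValueError):
    """A statistic is undefined for the given input (e.g. zero variance)."""


class CollinearityError(DataError):
    """A regression design matrix is rank deficient."""

    def __init__(self, terms):
        self.terms = list(terms)
        super().__init__(f"design matrix is rank deficient; collinear terms: {self.terms}")


class PipelineStageError(TractRiskError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
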