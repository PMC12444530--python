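"""Exception hierarchy for enthalpograph."""


class EnthalpographError(Exception):
    """Base class for all package-specific errors."""


class SmilesParseError(EnthalpographError):
    """The SMILES string could not be parsed."""


class UnsupportedInputError(EnthalpographError):
    """Input outside the supported subset (e.g. multi-fragment SMILES)."""


class UnsupportedElementError(EnthalpographError):
    """An element outside the supported organic subset was encountered."""


class ValenceError(EnthalpographError):
    """Implicit-hydrogen bookkeeping produced a negative count."""


class DisconnectedGraphError(EnthalpographError):
    """A distance-based quantity was requested on a disconnected graph."""


class ConvergenceError(EnthalpographError):
    """An iterative solver failed to converge."""


class ConstantColumnError(EnthalpographError):
    """Pearson correlation is undefined for a constant column."""


class MetricDomainError(EnthalpographError):
    """Metric preconditions violated (zero actuals for MAPE, negatives for RMSLE)."""


class RankDeficiencyError(EnthalpographError):
    """Singular normal equations in a linear fit."""


class NotFittedError(EnthalpographError):
    """Operation requires a fitted model."""


class UndefinedValidityError(EnthalpographError):
    """Cluster validity needs at least two non-noise clusters."""


class SchemaError(EnthalpographError):
    """A dataset file is missing required columns or has invalid rows."""
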