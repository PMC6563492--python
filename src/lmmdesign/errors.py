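"""Exception hierarchy for design, model and configuration errors."""


class LMMDesignError(Exception):
    """Base class for all package errors."""


class SpecificationError(LMMDesignError):
    """A model or design specification violates its invariants."""


class InvalidDesignError(LMMDesignError):
    """A design violates structural constraints (ordering, weights, region)."""


class CovarianceError(LMMDesignError):
    """A response covariance matrix is not (numerically) positive definite."""


class DropoutModelError(LMMDesignError):
    """A response-probability function leaves [0,1] or is non-monotone."""


class InfeasibleError(LMMDesignError):
    """No feasible point exists for a design-search problem."""


class EstimationError(LMMDesignError):
    """Available-case estimation failed (singular pooled information)."""


class ConfigError(LMMDesignError):
    """A run configuration failed schema validation."""
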