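"""Exception types shared across the pipeline."""


class ParameterError(ValueError):
    """Invalid parameter value (non-positive size, out-of-range rate, ...)."""


class GeometryError(ValueError):
    """Invalid or inconsistent 2D geometry (self-intersection, contour containment)."""


class DesignError(ValueError):
    """Statistical design problem (constant regressor, missing cells, unbalanced RM design)."""


class SolverError(RuntimeError):
    """Linear-system or time-stepping failure (singular system, no Dirichlet nodes)."""


class ConfigurationError(ValueError):
    """Unusable numerical configuration (e.g. unstable explicit time step)."""
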