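"""Exception hierarchy shared across the package."""


class RlfluxError(Exception):
    """Base class for all package-specific errors."""


class ModelParseError(RlfluxError):
    """A model file parsed syntactically but violated a structural invariant."""


class ConfigurationError(RlfluxError):
    """A medium source, objective id, or pipeline setting could not be resolved."""


class EngineeringError(RlfluxError):
    """A pathway graft could not be applied (e.g. duplicate reaction id)."""


class SolverError(RlfluxError):
    """The underlying linear program was infeasible or unbounded when a
    solution was required."""


class InputError(RlfluxError):
    """Malformed numeric input (NaNs, out-of-range p-values, shape mismatch)."""
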