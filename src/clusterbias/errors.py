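"""Exception hierarchy shared across the package."""


class ClusterBiasError(Exception):
    """Base class for all clusterbias errors."""


class SchemaError(ClusterBiasError):
    """A file does not match the documented dialect (e.g. a missing column)."""


class ValidationError(ClusterBiasError):
    """A value violates a type invariant or an operation precondition."""


class ConvergenceError(ClusterBiasError):
    """A model fit did not converge; inspect the fit diagnostics."""
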