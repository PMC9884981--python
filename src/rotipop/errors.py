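"""Exception hierarchy shared across the package."""


class RotipopError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(RotipopError, ValueError):
    """A simulation or pipeline configuration violates its invariants."""


class DataIntegrityError(RotipopError, ValueError):
    """Input data violate a structural contract (e.g. survivors increase)."""


class UndefinedQuantityError(RotipopError, ValueError):
    """A requested quantity is undefined for the given input (e.g. T at R0=0)."""


class SolverFailureError(RotipopError, RuntimeError):
    """A numerical solver could not bracket or converge on a root."""
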