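"""Exception hierarchy shared across the package."""


class HospDEAError(Exception):
    """Base class for all package errors."""


class SchemaError(HospDEAError):
    """A panel file is missing declared columns or is otherwise unreadable."""


class PanelValidationError(HospDEAError):
    """A record or panel violates a hard invariant (negative counts, duplicate keys)."""


class MissingOutputError(HospDEAError):
    """A DMU-matrix selector hit a field marked unavailable on some record."""

    def __init__(self, field: str, keys=None):
        self.field = field
        self.keys = list(keys or [])
        msg = f"output field {field!r} is unavailable"
        if self.keys:
            msg += f" for {len(self.keys)} record(s), e.g. {self.keys[0]}"
        super().__init__(msg)


class SolverError(HospDEAError):
    """The LP solver failed or returned an inconsistent solution."""


class DegenerateSampleError(HospDEAError):
    """A sample is too small or too uniform for the requested estimator."""


class CollinearityError(HospDEAError):
    """Design matrix is rank deficient."""
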