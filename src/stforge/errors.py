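"""Exception hierarchy for stforge.

All package-raised errors derive from :class:`StforgeError` so callers can
catch everything with one except clause; :class:`InvalidArgumentError`
subclasses ``ValueError`` so plain argument validation behaves as users of
numpy/scipy expect.
"""


class StforgeError(Exception):
    """Base class for all stforge errors."""


class InvalidArgumentError(StforgeError, ValueError):
    """An argument violates a precondition (bad shape, range, or value)."""


class DegenerateMetricError(InvalidArgumentError):
    """The chosen distance metric is degenerate on the given coordinates
    (e.g. cosine distance when all points are colinear with the origin)."""


class MissingTypeError(StforgeError, KeyError):
    """Requested cell types are absent from an expression reference."""

    def __init__(self, missing):
        self.missing = sorted(str(m) for m in missing)
        super().__init__(
            "cell types absent from reference: " + ", ".join(self.missing)
        )


class SchemaError(StforgeError, ValueError):
    """An on-disk dataset fails validation (dimension mismatch, bad header)."""


class ConfigError(StforgeError, ValueError):
    """A run configuration is malformed (unknown key, bad value)."""
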