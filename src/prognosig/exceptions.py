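"""Exception hierarchy for prognosig."""


class PrognosigError(Exception):
    """Base class for all package-specific errors."""


class IngestError(PrognosigError):
    """A file or table violates an ingest invariant.

    Ingest never repairs data silently: duplicate identifiers, missing
    cells, negative follow-up times etc. raise this error instead.
    """


class ModelIOError(PrognosigError):
    """A serialized model could not be read (truncated file, schema
    version mismatch, missing fields)."""


class NotFittedError(PrognosigError):
    """An operation that requires a trained model was called on an
    untrained one."""


class ConvergenceError(PrognosigError):
    """A Cox fit failed to converge (typically monotone separation,
    where the partial likelihood diverges as a coefficient grows
    without bound)."""


class QCError(PrognosigError):
    """A chip cannot be evaluated by the quality-control metrics."""
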