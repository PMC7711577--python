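"""Exception types shared across the pipeline."""


class GctFormatError(ValueError):
    """The file does not conform to the GCT 1.2 dialect."""


class ValidationError(ValueError):
    """A domain-object invariant is violated (e.g. negative TPM)."""


class EmptyGeneSetError(ValueError):
    """A gene-set source yielded zero usable gene symbols."""


class DegenerateMatrixError(ValueError):
    """The expression matrix cannot support the requested computation
    (all-zero values, or removal would delete every gene)."""


class ConvergenceError(RuntimeError):
    """Iterative maximum-likelihood fitting failed to converge."""
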