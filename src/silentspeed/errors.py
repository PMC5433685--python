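"""Exception types shared across the pipeline.

Validation failures (bad inputs, malformed files, impossible parameter
combinations) raise :class:`ValidationError`; iterative fits that fail to
converge raise :class:`ConvergenceError`.  The CLI maps these to exit codes
2 and 3 respectively.
"""


class ValidationError(ValueError):
    """Input or configuration violates a documented precondition."""


class ConvergenceError(RuntimeError):
    """A nonlinear fit failed to converge; diagnostics in ``args``."""
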