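"""Exception hierarchy for asersim."""


class AsersimError(Exception):
    """Base class for all asersim errors."""


class InvalidStateError(AsersimError):
    """A model state or input is non-finite or otherwise invalid."""


class IntegrationError(AsersimError):
    """The adaptive integrator failed (step-size underflow)."""

    def __init__(self, message: str, t_fail: float):
        super().__init__(f"{message} (at t = {t_fail:.6g} s)")
        self.t_fail = t_fail


class InvalidProtocolError(AsersimError):
    """A stimulus protocol violates its construction constraints."""


class DegenerateNormalizationError(AsersimError):
    """Min-max normalization of a constant trace is undefined."""


class InvalidBaselineError(AsersimError):
    """The pre-stimulus baseline is unusable (empty window or F0 <= 0)."""


class AlignmentError(AsersimError):
    """Two trace sets are not sampled on the same time grid."""


class UndefinedVAFError(AsersimError):
    """VAF is undefined because the reference trace has zero variance."""


class GenomeError(AsersimError):
    """A genetic-algorithm genome has the wrong length or alphabet."""


class GridOverflowError(AsersimError):
    """A parameter grid exceeds the configured enumeration cap."""
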