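"""Exception types shared across the association methods."""


class MonomorphicInputError(ValueError):
    """Raised when a genotype vector (or trait) is constant.

    A monomorphic locus carries no association information; the methods refuse
    to analyze it rather than silently returning p = 1, so that null
    distributions are never diluted by degenerate replicates.
    """


class RankDeficientError(ValueError):
    """Raised when the trait matrix is not of full column rank."""


class ConvergenceError(RuntimeError):
    """Raised when an iterative fit fails to converge.

    Carries diagnostics so callers (e.g. the evaluation harness) can count and
    report failures instead of crashing a whole study.
    """

    def __init__(self, message, *, n_iter=None, grad_norm=None):
        super().__init__(message)
        self.n_iter = n_iter
        self.grad_norm = grad_norm
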