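"""Run-time configuration shared across the pipeline.

Every switch that resolves an ambiguity in the scoring scheme lives here so
that a single object documents the exact variant of the method being run.
"""

from __future__ import annotations

import dataclasses
import logging

logger = logging.getLogger("kfpm")


@dataclasses.dataclass
class KFPMConfig:
    """Parameters of the ranking pipeline.

    Attributes
    ----------
    theta:
        Weight of the biological feature score against the topological score
        when forming initial node scores, in (0, 1). Default 0.7.
    alpha:
        Restart parameter of the propagation iteration, in (0, 1).
        Default 0.5.
    eps:
        Convergence threshold on the squared L2 norm of successive score
        differences.
    max_iter:
        Iteration cap; exceeding it raises a convergence error.
    wpp_exponent:
        Exponent applied to the common-neighbour count in the weighted PPI
        edge formula. The standard scheme squares the count (default 2);
        exponent 1 gives the plain normalised-overlap variant.
    wdd_sqrt_denominator:
        If True, the domain-domain weight divides by the geometric mean of
        the two domain sizes (cosine-like) instead of their product.
    critic_raw:
        If True, CRITIC weighting and the weighted feature sum operate on the
        raw feature columns instead of min-max scaled ones.
    top_on_ppi_only:
        If True, the topology score is computed on the protein-protein block
        only, ignoring domain nodes.
    dampen_exponent:
        Exponent on the (1 + max) denominator used to dampen each weight
        block before building the transition matrix.
    row_renorm:
        If True (default), every nonzero row of the assembled transition
        matrix is renormalised to sum to 1 so the iteration is a proper
        random walk with restart. If False the literal score-biased matrix
        is iterated unchanged.
    """

    theta: float = 0.7
    alpha: float = 0.5
    eps: float = 1e-6
    max_iter: int = 1000
    wpp_exponent: int = 2
    wdd_sqrt_denominator: bool = False
    critic_raw: bool = False
    top_on_ppi_only: bool = False
    dampen_exponent: int = 2
    row_renorm: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.theta < 1.0:
            raise ValueError(f"theta must lie in (0, 1), got {self.theta}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")


class KFPMError(Exception):
    """Base class for errors raised by this package."""


class InputFormatError(KFPMError):
    """Malformed input table; message names the offending line."""


class ConvergenceError(KFPMError):
    """Propagation failed to converge within the iteration cap."""

    def __init__(self, message: str, residual: float, iterations: int):
        super().__init__(message)
        self.residual = residual
        self.iterations = iterations
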