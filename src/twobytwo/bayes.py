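"""Posterior inference for the log odds ratio under conjugate Beta priors.

Independent priors Beta(a, a) are placed on the two success probabilities
(a = 1/2 for Jeffreys, a = 1 for uniform); the posterior of each is then a
Beta distribution, and the posterior of psi = logit(pi1) - logit(pi2) is
obtained by Monte Carlo.  Interval estimates are equal-tailed quantile
intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logit

from .tables import Table2x2

__all__ = ["PosteriorSpec", "posterior_psi_samples", "credible_interval"]

_PRIOR_A = {"jeffreys": 0.5, "uniform": 1.0}


@dataclass(frozen=True)
class PosteriorSpec:
    """Prior choice and Monte Carlo settings for posterior sampling."""

    prior: str = "jeffreys"
    draws: int = 100_000
    seed: int | None = None
    level: float = 0.95
    interval_type: str = "equal_tailed"

    def __post_init__(self) -> None:
        if self.prior not in _PRIOR_A:
            raise ValueError(f"prior must be one of {sorted(_PRIOR_A)}")
        if self.draws < 1000:
            raise ValueError("at least 1000 draws are required for interval estimation")
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must be in (0, 1)")
        if self.interval_type != "equal_tailed":
            raise ValueError("only equal-tailed intervals are supported")


def posterior_psi_samples(table: Table2x2, spec: PosteriorSpec) -> np.ndarray:
    """Draw from the posterior of the log odds ratio.

    pi1 ~ Beta(y1+a, n1-y1+a) and pi2 ~ Beta(y2+a, n2-y2+a) independently;
    psi = logit(pi1) - logit(pi2).  Draws are almost surely interior, so
    psi is finite.  Reproducible given the seed.
    """
    a = _PRIOR_A[spec.prior]
    rng = np.random.default_rng(spec.seed)
    pi1 = rng.beta(table.y1 + a, table.n1 - table.y1 + a, size=spec.draws)
    pi2 = rng.beta(table.y2 + a, table.n2 - table.y2 + a, size=spec.draws)
    return np.asarray(logit(pi1) - logit(pi2))


def credible_interval(samples: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed empirical quantile interval at the given level."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    samples = np.asarray(samples)
    if samples.size < 1000:
        raise ValueError("too few samples for a stable quantile interval")
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(samples, [tail, 1.0 - tail])
    return float(lo), float(hi)
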