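"""Likelihood objects for the dual-binomial 2x2 table model.

The full likelihood of a table factorizes, in the canonical parameterization
``(psi, lambda)`` with ``psi`` the log odds ratio and ``lambda = logit(pi2)``,
into a conditional piece (the noncentral hypergeometric likelihood of ``y1``
given the success total ``y+``, free of the nuisance) and a marginal piece
(the likelihood of ``y+`` alone):

    f(y1, y2; psi, lambda) = f(y1 | y+; psi) * f(y+; psi, lambda).

This module evaluates every piece in log space, together with the pseudo-
likelihoods built from the full likelihood — profile, estimated (plug-in),
and modified profile — and the conditional MLE of ``psi``.  All arithmetic
is in log space; curves are standardized by subtracting the log-maximum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, gammaln, logsumexp
from scipy.stats import binom

from .tables import ParamPoint, Table2x2, psi_hat_unconditional

__all__ = [
    "LikelihoodCurve",
    "PoissonTable",
    "loglik_full",
    "log_normalizer",
    "loglik_conditional",
    "loglik_marginal",
    "conditional_mle",
    "profile_loglik",
    "estimated_loglik",
    "modified_profile_loglik",
    "poisson_conditional_logpmf",
    "likelihood_curve",
]


def _log_binom(n: int, k) -> np.ndarray | float:
    """log of the binomial coefficient C(n, k), vectorized over k."""
    k = np.asarray(k, dtype=float)
    out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return out if out.shape else float(out)


def loglik_full(table: Table2x2, point: ParamPoint) -> float:
    """Log of the product-binomial pmf at an interior parameter point."""
    return float(
        binom.logpmf(table.y1, table.n1, point.pi1)
        + binom.logpmf(table.y2, table.n2, point.pi2)
    )


def loglik_full_canonical(table: Table2x2, psi: float, lam: float) -> float:
    """Same pmf written in the exponential-family form.

    ``exp(psi*y1 + lambda*y+) / [(1+e^(psi+lambda))^n1 (1+e^lambda)^n2]``
    times the binomial coefficients; numerically robust for large |psi|,
    |lambda| via log1p/logaddexp.
    """
    return float(
        _log_binom(table.n1, table.y1)
        + _log_binom(table.n2, table.y2)
        + psi * table.y1
        + lam * table.y_plus
        - table.n1 * np.logaddexp(0.0, psi + lam)
        - table.n2 * np.logaddexp(0.0, lam)
    )


def _support(y_plus: int, n1: int, n2: int) -> np.ndarray:
    lo = max(0, y_plus - n2)
    hi = min(n1, y_plus)
    return np.arange(lo, hi + 1)


def log_normalizer(psi: float, y_plus: int, n1: int, n2: int) -> float:
    """log C(psi, y+) = log sum_u C(n1,u) C(n2,y+-u) exp(psi*u).

    The sum runs over the conditioned support of y1.  Computed by
    log-sum-exp, so it is stable for |psi| in the hundreds where a naive
    sum would overflow.
    """
    if not 0 <= y_plus <= n1 + n2:
        raise ValueError(f"y_plus={y_plus} out of range [0, {n1 + n2}]")
    if not math.isfinite(psi):
        raise ValueError("psi must be finite")
    u = _support(y_plus, n1, n2)
    terms = _log_binom(n1, u) + _log_binom(n2, y_plus - u) + psi * u
    return float(logsumexp(terms))


def loglik_conditional(table: Table2x2, psi: float) -> float:
    """Noncentral hypergeometric log-pmf of y1 given y+ at log odds ratio psi.

    At ``psi = 0`` this is the (central) hypergeometric pmf underlying
    Fisher's exact test.
    """
    return float(
        _log_binom(table.n1, table.y1)
        + _log_binom(table.n2, table.y2)
        + psi * table.y1
        - log_normalizer(psi, table.y_plus, table.n1, table.n2)
    )


def loglik_marginal(y_plus: int, n1: int, n2: int, point: ParamPoint) -> float:
    """Log-pmf of the success total y+ at an interior parameter point.

    ``f(y+; psi, lambda) = exp(lambda*y+) (1+e^(psi+lambda))^-n1
    (1+e^lambda)^-n2 C(psi, y+)``.  Nearly flat in psi — the reason
    conditioning on y+ loses little information about the odds ratio.
    """
    if not 0 <= y_plus <= n1 + n2:
        raise ValueError(f"y_plus={y_plus} out of range [0, {n1 + n2}]")
    psi, lam = point.psi, point.lambda_can
    return float(
        lam * y_plus
        - n1 * np.logaddexp(0.0, psi + lam)
        - n2 * np.logaddexp(0.0, lam)
        + log_normalizer(psi, y_plus, n1, n2)
    )


def _tilted_mean(psi: float, y_plus: int, n1: int, n2: int) -> float:
    """E_psi[Y1 | y+] under the noncentral hypergeometric distribution."""
    u = _support(y_plus, n1, n2)
    logw = _log_binom(n1, u) + _log_binom(n2, y_plus - u) + psi * u
    logw = logw - logsumexp(logw)
    return float(np.exp(logw) @ u)


def conditional_mle(table: Table2x2) -> float:
    """MLE of psi under the conditional (noncentral hypergeometric) likelihood.

    Interior solutions solve the mean equation ``E_psi[Y1 | y+] = y1``,
    which is strictly increasing in psi; at the ends of the conditioned
    support the MLE is ``-inf`` / ``+inf``.
    """
    sup = _support(table.y_plus, table.n1, table.n2)
    if len(sup) == 1:
        return 0.0  # degenerate support: likelihood constant in psi
    if table.y1 == sup[0]:
        return -math.inf
    if table.y1 == sup[-1]:
        return math.inf

    def score(psi: float) -> float:
        return _tilted_mean(psi, table.y_plus, table.n1, table.n2) - table.y1

    lo, hi = -1.0, 1.0
    while score(lo) > 0:
        lo *= 2.0
    while score(hi) < 0:
        hi *= 2.0
    return float(brentq(score, lo, hi, xtol=1e-12))


def _lambda_hat_given_psi(table: Table2x2, psi: float) -> float:
    """Constrained MLE of the canonical nuisance at fixed psi.

    Solves the score equation ``y+ = n1*expit(psi+lambda) + n2*expit(lambda)``
    (strictly increasing in lambda).  Requires 0 < y+ < n+; at the margins
    the constrained MLE escapes to -inf/+inf and no interior root exists.
    """
    if table.y_plus == 0 or table.y_plus == table.n_plus:
        raise ValueError("constrained nuisance MLE does not exist for degenerate y+")

    def score(lam: float) -> float:
        return table.n1 * expit(psi + lam) + table.n2 * expit(lam) - table.y_plus

    lo, hi = -50.0, 50.0
    while score(lo) > 0:
        lo *= 2.0
    while score(hi) < 0:
        hi *= 2.0
    return float(brentq(score, lo, hi, xtol=1e-13))


def profile_loglik(table: Table2x2, psi: float) -> float:
    """Full log-likelihood maximized over the nuisance at fixed psi."""
    if table.y_plus == 0:
        # likelihood maximized in the limit lambda -> -inf; sup equals 0
        return 0.0
    if table.y_plus == table.n_plus:
        return 0.0
    lam = _lambda_hat_given_psi(table, psi)
    return loglik_full_canonical(table, psi, lam)


def estimated_loglik(table: Table2x2, psi: float) -> float:
    """Plug-in log-likelihood: full likelihood at (psi, global lambda*-hat).

    The orthogonal nuisance lambda* has global MLE y+/n+ regardless of psi,
    so the plug-in curve evaluates the full likelihood along the slice
    lambda* = y+/n+.
    """
    if table.y_plus == 0 or table.y_plus == table.n_plus:
        return 0.0
    lam_star = table.y_plus / table.n_plus
    pt = ParamPoint.from_orthogonal(psi, lam_star, table.n1, table.n2)
    return loglik_full_canonical(table, psi, pt.lambda_can)


def modified_profile_loglik(table: Table2x2, psi: float) -> float:
    """Profile log-likelihood with the canonical curvature adjustment.

    ``lp(psi) + 0.5 * log j_ll(psi, lambda_hat_psi)`` where
    ``j_ll = n1*pi1*(1-pi1) + n2*pi2*(1-pi2)`` is the observed information
    for the canonical nuisance at its constrained MLE.  For a linear
    exponential family with canonical nuisance, Barndorff-Nielsen's formula
    reduces to ``L_p * |j_ll(psi, lam_hat_psi)|^{-1/2} *
    |d lam_hat / d lam_hat_psi|``; the sample-space Jacobian equals
    ``j_ll(psi, lam_hat_psi) / j_ll(psi_hat, lam_hat)``, so up to a
    psi-free constant the net exponent on the curvature is +1/2.  The
    resulting curve tracks the conditional likelihood closely even at
    tiny sample sizes.
    """
    if table.y_plus == 0 or table.y_plus == table.n_plus:
        raise ValueError("modified profile likelihood undefined for degenerate y+")
    lam = _lambda_hat_given_psi(table, psi)
    pi1 = float(expit(psi + lam))
    pi2 = float(expit(lam))
    j_ll = table.n1 * pi1 * (1.0 - pi1) + table.n2 * pi2 * (1.0 - pi2)
    return loglik_full_canonical(table, psi, lam) + 0.5 * math.log(j_ll)


@dataclass(frozen=True)
class PoissonTable:
    """2x2 table of Poisson cell counts m_ij with means mu_ij."""

    m11: int
    m12: int
    m21: int
    m22: int
    mu11: float
    mu12: float
    mu21: float
    mu22: float

    def __post_init__(self) -> None:
        if min(self.m11, self.m12, self.m21, self.m22) < 0:
            raise ValueError("cell counts must be non-negative")
        if min(self.mu11, self.mu12, self.mu21, self.mu22) <= 0:
            raise ValueError("cell means must be positive")

    @property
    def m1_plus(self) -> int:
        return self.m11 + self.m12

    @property
    def m2_plus(self) -> int:
        return self.m21 + self.m22


def poisson_conditional_logpmf(pt: PoissonTable) -> float:
    """Log-pmf of four Poisson cells conditioned on the row totals.

    Conditioning independent Poisson counts on the row margins turns each
    row into a binomial with success probability mu_i1/(mu_i1+mu_i2) —
    recovering the dual-binomial model with n1 = m1+, n2 = m2+.
    """
    p1 = pt.mu11 / (pt.mu11 + pt.mu12)
    p2 = pt.mu21 / (pt.mu21 + pt.mu22)
    return float(
        binom.logpmf(pt.m11, pt.m1_plus, p1) + binom.logpmf(pt.m21, pt.m2_plus, p2)
    )


_CURVE_KINDS: dict[str, Callable[[Table2x2, float], float]] = {
    "conditional": loglik_conditional,
    "profile": profile_loglik,
    "estimated": estimated_loglik,
    "modified_profile": modified_profile_loglik,
}


@dataclass(frozen=True)
class LikelihoodCurve:
    """A likelihood evaluated on a psi grid, with standardized values."""

    kind: str
    psi: np.ndarray
    loglik: np.ndarray

    def __post_init__(self) -> None:
        psi = np.asarray(self.psi, dtype=float)
        ll = np.asarray(self.loglik, dtype=float)
        if psi.ndim != 1 or psi.shape != ll.shape:
            raise ValueError("psi and loglik must be 1-D arrays of equal length")
        if np.any(np.diff(psi) <= 0):
            raise ValueError("psi grid must be strictly increasing")
        object.__setattr__(self, "psi", psi)
        object.__setattr__(self, "loglik", ll)

    @property
    def standardized(self) -> np.ndarray:
        """Likelihood ratio to the maximum over the grid, in (0, 1]."""
        return np.exp(self.loglik - self.loglik.max())

    @property
    def psi_max(self) -> float:
        """Grid location of the maximum."""
        return float(self.psi[int(np.argmax(self.loglik))])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"psi": self.psi, "loglik": self.loglik, "standardized": self.standardized}
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def likelihood_curve(
    table: Table2x2,
    kind: str = "conditional",
    psi_grid: Optional[np.ndarray] = None,
    n_points: int = 401,
    half_width: float = 8.0,
    clip: float = 12.0,
) -> LikelihoodCurve:
    """Evaluate one of the psi-likelihoods on a grid.

    The default grid spans ``psi_hat_c +/- half_width`` clipped to
    ``[-clip, clip]`` (centered at 0 when the conditional MLE is infinite).
    """
    if kind not in _CURVE_KINDS:
        raise ValueError(f"unknown curve kind {kind!r}; expected one of {sorted(_CURVE_KINDS)}")
    if psi_grid is None:
        center = conditional_mle(table)
        if not math.isfinite(center):
            center = 0.0
        lo = max(-clip, center - half_width)
        hi = min(clip, center + half_width)
        psi_grid = np.linspace(lo, hi, n_points)
    fn = _CURVE_KINDS[kind]
    ll = np.array([fn(table, float(p)) for p in psi_grid])
    return LikelihoodCurve(kind=kind, psi=np.asarray(psi_grid, dtype=float), loglik=ll)
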