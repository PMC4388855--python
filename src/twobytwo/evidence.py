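"""Tests, p-values, likelihood ratios, and support intervals for a 2x2 table.

Implements the classical toolkit side by side so the evidence in one table
can be compared across paradigms: Pearson chi-square (with and without the
Yates continuity correction), Fisher's exact test (one-sided, probability-
ordered two-sided, and doubled one-sided), the mid-p correction, Tocher's
randomized exact test, the conditional likelihood-ratio test, and 1/k
likelihood support intervals from the conditional, profile, or modified
profile likelihood.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2 as chi2_dist

from .likelihoods import (
    conditional_mle,
    loglik_conditional,
    modified_profile_loglik,
    profile_loglik,
)
from .tables import Table2x2, psi_hat_unconditional

__all__ = [
    "TestResult",
    "SupportInterval",
    "EvidenceReport",
    "pearson_chi2",
    "fisher_exact",
    "mid_p",
    "tocher_test",
    "conditional_lr_test",
    "support_interval",
    "analyze",
]

# relative tolerance for declaring two hypergeometric pmf values tied when
# probability-ordering a discrete two-sided tail
_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test on one table."""

    method: str
    p_value: float
    statistic: Optional[float] = None
    sidedness: str = "two_sided"
    gamma: Optional[float] = None  # Tocher rejection probability at the boundary outcome
    reject: Optional[bool] = None  # Tocher randomized decision
    df: Optional[int] = None

    def __post_init__(self) -> None:
        if not -1e-12 <= self.p_value <= 1 + 1e-12:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        object.__setattr__(self, "p_value", float(min(1.0, max(0.0, self.p_value))))


def pearson_chi2(table: Table2x2, continuity_correction: bool = False) -> TestResult:
    """Pearson chi-square test of independence, 1 df.

    The continuity correction subtracts n+/2 from |ad - bc| (floored at 0).
    """
    a, b, c, d = table.cells()
    n1, n2 = table.n1, table.n2
    y_plus, n_plus = table.y_plus, table.n_plus
    if y_plus == 0 or y_plus == n_plus:
        raise ValueError("statistic undefined for degenerate margin")
    cross = abs(a * d - b * c)
    corr = n_plus / 2.0 if continuity_correction else 0.0
    cross = max(0.0, cross - corr)
    stat = n_plus * cross**2 / (n1 * n2 * y_plus * (n_plus - y_plus))
    p = float(chi2_dist.sf(stat, df=1))
    name = "pearson_chi2_yates" if continuity_correction else "pearson_chi2"
    return TestResult(method=name, p_value=p, statistic=float(stat), df=1)


def _null_logpmf_support(table: Table2x2) -> tuple[np.ndarray, np.ndarray]:
    """Central hypergeometric log-pmf of Y1 over the conditioned support."""
    y_plus, n1, n2 = table.y_plus, table.n1, table.n2
    u = np.arange(max(0, y_plus - n2), min(n1, y_plus) + 1)

    def lb(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    logpmf = lb(n1, u) + lb(n2, y_plus - u) - lb(n1 + n2, y_plus)
    return u, logpmf


def fisher_exact(table: Table2x2, alternative: str = "two_sided_prob") -> TestResult:
    """Fisher's exact test from the central hypergeometric distribution.

    alternatives:
      ``less`` / ``greater``   one-sided tail in y1
      ``two_sided_prob``       probability ordering (sum pmf <= pmf observed)
      ``two_sided_doubled``    twice the smaller one-sided p, capped at 1
    """
    u, logpmf = _null_logpmf_support(table)
    pmf = np.exp(logpmf)
    obs = table.y1
    p_obs = float(pmf[u == obs][0])
    if alternative == "less":
        p = float(pmf[u <= obs].sum())
    elif alternative == "greater":
        p = float(pmf[u >= obs].sum())
    elif alternative == "two_sided_prob":
        p = float(pmf[pmf <= p_obs * (1.0 + _TIE_RTOL)].sum())
    elif alternative == "two_sided_doubled":
        p_less = float(pmf[u <= obs].sum())
        p_greater = float(pmf[u >= obs].sum())
        p = min(1.0, 2.0 * min(p_less, p_greater))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    side = "one_sided" if alternative in ("less", "greater") else "two_sided"
    return TestResult(method=f"fisher_{alternative}", p_value=min(1.0, p), sidedness=side)


def mid_p(table: Table2x2, alternative: str = "two_sided") -> TestResult:
    """Mid-p-value: only half the probability of the observed outcome counts.

    Mitigates the conservatism exact tests inherit from a discrete sample
    space.  One-sided: P(strictly more extreme) + P(observed)/2.  Two-sided
    (probability ordering): the pmf of strictly-less-likely outcomes plus
    half the pmf of outcomes tied with the observed one.
    """
    u, logpmf = _null_logpmf_support(table)
    pmf = np.exp(logpmf)
    obs = table.y1
    p_obs = float(pmf[u == obs][0])
    if alternative == "less":
        p = float(pmf[u < obs].sum()) + 0.5 * p_obs
    elif alternative == "greater":
        p = float(pmf[u > obs].sum()) + 0.5 * p_obs
    elif alternative == "two_sided":
        tied = np.abs(pmf - p_obs) <= p_obs * _TIE_RTOL
        below = pmf < p_obs * (1.0 - _TIE_RTOL)
        p = float(pmf[below].sum()) + 0.5 * float(pmf[tied].sum())
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    side = "two_sided" if alternative == "two_sided" else "one_sided"
    return TestResult(method=f"mid_p_{alternative}", p_value=min(1.0, p), sidedness=side)


def tocher_test(
    table: Table2x2,
    alpha: float = 0.05,
    seed: Optional[int] = None,
    alternative: Optional[str] = None,
) -> TestResult:
    """Tocher's randomized exact test attaining the nominal size exactly.

    With ``P_ex`` the null probability of strictly more extreme outcomes in
    the chosen tail and ``P_obs`` the probability of the observed outcome:
    reject when ``P_ex + P_obs <= alpha``; accept when ``P_ex > alpha``;
    otherwise reject with probability ``gamma = (alpha - P_ex) / P_obs``
    using the seeded generator.  Averaged over the conditional null this
    rejects with probability exactly alpha.

    ``alternative`` defaults to the one-sided tail toward the observed
    deviation from the conditional null mean.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    u, logpmf = _null_logpmf_support(table)
    pmf = np.exp(logpmf)
    if alternative is None:
        null_mean = float(pmf @ u)
        alternative = "less" if table.y1 <= null_mean else "greater"
    if alternative == "less":
        p_ex = float(pmf[u < table.y1].sum())
    elif alternative == "greater":
        p_ex = float(pmf[u > table.y1].sum())
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p_obs = float(pmf[u == table.y1][0])
    if p_ex + p_obs <= alpha:
        gamma, reject = 1.0, True
    elif p_ex > alpha:
        gamma, reject = 0.0, False
    else:
        gamma = (alpha - p_ex) / p_obs
        rng = np.random.default_rng(seed)
        reject = bool(rng.random() < gamma)
    return TestResult(
        method="tocher",
        p_value=min(1.0, p_ex + p_obs),
        sidedness="one_sided",
        gamma=gamma,
        reject=reject,
    )


def conditional_lr_test(table: Table2x2) -> TestResult:
    """Likelihood-ratio test from the conditional likelihood.

    Statistic ``-2 [l_c(0) - l_c(psi_hat_c)]`` referred to chi-square 1 df.
    When the conditional MLE is infinite the supremum of the conditional
    likelihood equals 1 (a point mass at the boundary configuration), so
    the statistic reduces to ``-2 l_c(0)``.
    """
    psi_hat = conditional_mle(table)
    ll0 = loglik_conditional(table, 0.0)
    if math.isfinite(psi_hat):
        stat = -2.0 * (ll0 - loglik_conditional(table, psi_hat))
    else:
        stat = -2.0 * ll0
    stat = max(0.0, stat)
    p = float(chi2_dist.sf(stat, df=1))
    return TestResult(method="conditional_lr", p_value=p, statistic=float(stat), df=1)


_SI_LIKELIHOODS = {
    "conditional": loglik_conditional,
    "profile": profile_loglik,
    "modified_profile": modified_profile_loglik,
}

# |psi| beyond which a standardized likelihood is treated as at its limit
_PSI_LIMIT = 500.0


@dataclass(frozen=True)
class SupportInterval:
    """The set of psi whose standardized likelihood exceeds 1/k."""

    k: float
    which: str
    lower: float
    upper: float
    mle: float

    def __contains__(self, psi: float) -> bool:
        return self.lower <= psi <= self.upper

    def covers(self, psi: float) -> bool:
        return self.lower <= psi <= self.upper


def _maximize_curve(table: Table2x2, which: str) -> tuple[float, float]:
    """(psi_hat, max loglik) for the named psi-likelihood."""
    fn = _SI_LIKELIHOODS[which]
    if which == "conditional":
        psi_hat = conditional_mle(table)
    elif which == "profile":
        psi_hat = psi_hat_unconditional(table)
    else:
        from scipy.optimize import minimize_scalar

        # bracket around the conditional MLE, which the modified profile tracks
        center = conditional_mle(table)
        if not math.isfinite(center):
            psi_hat = center
        else:
            res = minimize_scalar(
                lambda p: -fn(table, p),
                bounds=(center - 6.0, center + 6.0),
                method="bounded",
                options={"xatol": 1e-10},
            )
            psi_hat = float(res.x)
    if math.isfinite(psi_hat):
        return psi_hat, fn(table, psi_hat)
    # supremum approached at the end of the range; evaluate at the limit proxy
    sign = 1.0 if psi_hat > 0 else -1.0
    return psi_hat, fn(table, sign * _PSI_LIMIT)


def support_interval(table: Table2x2, k: float, which: str = "conditional") -> SupportInterval:
    """1/k likelihood support interval from the chosen psi-likelihood.

    Endpoints solve standardized-likelihood = 1/k by bisection outward from
    the MLE (tolerance 1e-8 in psi).  An endpoint is +/-inf when the
    standardized likelihood stays above 1/k all the way to the limit.
    """
    if k <= 1.0:
        raise ValueError("support level k must exceed 1")
    if which not in _SI_LIKELIHOODS:
        raise ValueError(f"unknown likelihood {which!r}; expected one of {sorted(_SI_LIKELIHOODS)}")
    fn = _SI_LIKELIHOODS[which]
    psi_hat, ll_max = _maximize_curve(table, which)
    target = ll_max - math.log(k)

    def g(psi: float) -> float:
        return fn(table, psi) - target

    def solve(direction: float) -> float:
        start = psi_hat if math.isfinite(psi_hat) else direction * _PSI_LIMIT
        if not math.isfinite(psi_hat):
            # MLE at infinity: the limit side stays above 1/k
            if direction * psi_hat > 0:
                return psi_hat
            start = -direction * _PSI_LIMIT  # walk back from the far limit
        step = 0.5
        a = start
        while True:
            b = a + direction * step
            if abs(b) >= _PSI_LIMIT:
                if g(direction * _PSI_LIMIT) > 0:
                    return direction * math.inf
                b = direction * _PSI_LIMIT
                break
            if g(b) <= 0:
                break
            a = b
            step *= 2.0
        from scipy.optimize import brentq

        lo, hi = (a, b) if a < b else (b, a)
        return float(brentq(g, lo, hi, xtol=1e-8))

    lower = solve(-1.0)
    upper = solve(+1.0)
    return SupportInterval(k=float(k), which=which, lower=lower, upper=upper, mle=psi_hat)


@dataclass
class EvidenceReport:
    """Everything the package computes for one table, JSON-serializable."""

    table: Table2x2
    tests: list[TestResult] = field(default_factory=list)
    psi_hat_unconditional: float = math.nan
    psi_hat_conditional: float = math.nan
    lr_vs_null: float = math.nan
    support_intervals: list[SupportInterval] = field(default_factory=list)
    bayes_interval: Optional[dict] = None

    def to_dict(self) -> dict:
        return {
            "table": {"y1": self.table.y1, "n1": self.table.n1, "y2": self.table.y2, "n2": self.table.n2},
            "tests": [asdict(t) for t in self.tests],
            "psi_hat_unconditional": self.psi_hat_unconditional,
            "psi_hat_conditional": self.psi_hat_conditional,
            "lr_vs_null": self.lr_vs_null,
            "support_intervals": [asdict(s) for s in self.support_intervals],
            "bayes_interval": self.bayes_interval,
        }

    def to_json(self, **kwargs) -> str:
        def default(o):
            raise TypeError(o)

        return json.dumps(self.to_dict(), default=default, **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "EvidenceReport":
        return cls(
            table=Table2x2(**d["table"]),
            tests=[TestResult(**t) for t in d["tests"]],
            psi_hat_unconditional=d["psi_hat_unconditional"],
            psi_hat_conditional=d["psi_hat_conditional"],
            lr_vs_null=d["lr_vs_null"],
            support_intervals=[SupportInterval(**s) for s in d["support_intervals"]],
            bayes_interval=d.get("bayes_interval"),
        )

    @classmethod
    def from_json(cls, s: str) -> "EvidenceReport":
        return cls.from_dict(json.loads(s))

    def text_panel(self) -> str:
        """Human-readable summary in the layout of a p-value comparison table."""
        lines = [str(self.table), "", f"{'method':<28}{'p-value':>10}"]
        for t in self.tests:
            lines.append(f"{t.method:<28}{t.p_value:>10.4f}")
        lines.append("")
        lines.append(f"unconditional MLE psi-hat   {self.psi_hat_unconditional: .4f}")
        lines.append(f"conditional MLE psi-hat     {self.psi_hat_conditional: .4f}")
        lines.append(f"LR (MLE vs psi=0)           {self.lr_vs_null: .4f}")
        for si in self.support_intervals:
            lines.append(
                f"1/{si.k:g} SI ({si.which}): [{si.lower: .4f}, {si.upper: .4f}]"
            )
        if self.bayes_interval:
            bi = self.bayes_interval
            lines.append(
                f"{bi['level']:.0%} {bi['prior']} credible interval: "
                f"[{bi['lower']: .4f}, {bi['upper']: .4f}]"
            )
        return "\n".join(lines)


_DEFAULT_SI_LEVELS = (6.8, 8.0, 32.0)


def analyze(
    table: Table2x2,
    si_levels: tuple[float, ...] = _DEFAULT_SI_LEVELS,
    si_which: str = "conditional",
    tocher_alpha: float = 0.05,
    seed: Optional[int] = None,
) -> EvidenceReport:
    """Compute the full evidence report for one table."""
    degenerate = table.y_plus == 0 or table.y_plus == table.n_plus
    tests: list[TestResult] = []
    if not degenerate:
        tests.append(pearson_chi2(table, continuity_correction=False))
        tests.append(pearson_chi2(table, continuity_correction=True))
    tests.append(fisher_exact(table, "two_sided_prob"))
    less = fisher_exact(table, "less")
    greater = fisher_exact(table, "greater")
    tests.append(less if less.p_value <= greater.p_value else greater)
    tests.append(fisher_exact(table, "two_sided_doubled"))
    tests.append(mid_p(table, "two_sided"))
    tests.append(tocher_test(table, alpha=tocher_alpha, seed=seed))
    tests.append(conditional_lr_test(table))

    psi_c = conditional_mle(table)
    if math.isfinite(psi_c):
        lr = math.exp(loglik_conditional(table, psi_c) - loglik_conditional(table, 0.0))
    else:
        lr = math.exp(-loglik_conditional(table, 0.0))
    sis = [support_interval(table, k, si_which) for k in si_levels]
    return EvidenceReport(
        table=table,
        tests=tests,
        psi_hat_unconditional=psi_hat_unconditional(table),
        psi_hat_conditional=psi_c,
        lr_vs_null=lr,
        support_intervals=sis,
    )
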