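"""Frequency-property studies: type-I error of tests, coverage of intervals.

Tables are generated from the dual-binomial model Y1 ~ Binomial(n1, pi1),
Y2 ~ Binomial(n2, pi2).  Because a test decision depends on the data only
through (y1, y2), each study precomputes its decision rule once over the
(n1+1) x (n2+1) grid of possible tables and then tabulates the simulated
stream against it, which keeps tens of thousands of replicates cheap.

Degenerate replicates (y+ = 0 or y+ = n+), where most statistics are
undefined, are counted as non-rejections for tests and as covering for
intervals; the count of such replicates is reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np

from . import evidence
from .tables import Table2x2

__all__ = [
    "Scenario",
    "SimulationResult",
    "generate_tables",
    "type1_error",
    "interval_noncoverage",
]


@dataclass(frozen=True)
class Scenario:
    """One simulation scenario for the dual-binomial model."""

    pi1: float
    pi2: float
    n1: int
    n2: int
    reps: int = 20_000
    seed: Optional[int] = None
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.pi1 <= 1.0 and 0.0 <= self.pi2 <= 1.0):
            raise ValueError("pi1, pi2 must lie in [0, 1]")
        if self.n1 < 1 or self.n2 < 1 or self.reps < 1:
            raise ValueError("n1, n2, reps must be positive")
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")

    @property
    def is_null(self) -> bool:
        return self.pi1 == self.pi2

    @property
    def psi(self) -> float:
        """True log odds ratio of the scenario (extended real)."""
        for p in (self.pi1, self.pi2):
            if p in (0.0, 1.0):
                return math.nan
        return math.log(self.pi1 / (1 - self.pi1)) - math.log(self.pi2 / (1 - self.pi2))


@dataclass
class SimulationResult:
    """Per-method Monte Carlo proportions with standard errors."""

    scenario: Scenario
    proportions: dict[str, float]
    reps: int
    degenerate: int = 0
    extra: dict = field(default_factory=dict)

    def mcse(self, method: str) -> float:
        p = self.proportions[method]
        return math.sqrt(p * (1.0 - p) / self.reps)

    def to_rows(self) -> list[dict]:
        s = self.scenario
        return [
            {
                "pi1": s.pi1,
                "pi2": s.pi2,
                "n1": s.n1,
                "n2": s.n2,
                "reps": self.reps,
                "alpha": s.alpha,
                "method": m,
                "proportion": p,
                "mcse": self.mcse(m),
                "degenerate": self.degenerate,
            }
            for m, p in self.proportions.items()
        ]


def generate_tables(scenario: Scenario) -> Iterator[Table2x2]:
    """Stream of independent tables from the scenario, reproducible by seed."""
    for y1, y2 in _generate_counts(scenario):
        yield Table2x2(int(y1), scenario.n1, int(y2), scenario.n2)


def _generate_counts(scenario: Scenario) -> np.ndarray:
    rng = np.random.default_rng(scenario.seed)
    y1 = rng.binomial(scenario.n1, scenario.pi1, size=scenario.reps)
    y2 = rng.binomial(scenario.n2, scenario.pi2, size=scenario.reps)
    return np.column_stack([y1, y2])


# registry of named tests usable in type-I-error studies; each maps a table
# and alpha to a (possibly randomized) rejection probability in [0, 1]
def _pval_method(fn, **kw):
    def rule(table: Table2x2, alpha: float) -> float:
        try:
            return 1.0 if fn(table, **kw).p_value <= alpha else 0.0
        except ValueError:  # degenerate margin
            return 0.0

    return rule


def _tocher_rule(table: Table2x2, alpha: float) -> float:
    # fixed 'less' tail: choosing the tail from the data would double the size
    try:
        return evidence.tocher_test(table, alpha=alpha, seed=0, alternative="less").gamma
    except ValueError:
        return 0.0


METHODS = {
    "fisher_two_sided": _pval_method(evidence.fisher_exact, alternative="two_sided_prob"),
    "fisher_doubled": _pval_method(evidence.fisher_exact, alternative="two_sided_doubled"),
    "mid_p": _pval_method(evidence.mid_p, alternative="two_sided"),
    "pearson_chi2": _pval_method(evidence.pearson_chi2, continuity_correction=False),
    "pearson_chi2_yates": _pval_method(evidence.pearson_chi2, continuity_correction=True),
    "conditional_lr": _pval_method(evidence.conditional_lr_test),
    "tocher": _tocher_rule,
}


def type1_error(
    scenario: Scenario,
    methods: Sequence[str] = ("fisher_two_sided", "mid_p", "conditional_lr"),
) -> SimulationResult:
    """Rejection proportion of each test under a null scenario at level alpha.

    Tocher's randomized test contributes its rejection indicator drawn with
    the replicate's own substream, so its proportion is an unbiased estimate
    of the exact size alpha.
    """
    if not scenario.is_null:
        raise ValueError("type1_error requires a null scenario (pi1 == pi2)")
    return _rejection_study(scenario, methods)


def power(scenario: Scenario, methods: Sequence[str]) -> SimulationResult:
    """Rejection proportion under any (null or alternative) scenario."""
    return _rejection_study(scenario, methods)


def _rejection_study(scenario: Scenario, methods: Sequence[str]) -> SimulationResult:
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}; known: {sorted(METHODS)}")
    counts = _generate_counts(scenario)
    n1, n2, alpha = scenario.n1, scenario.n2, scenario.alpha
    # decision rule over the full grid of attainable tables
    grid = {}
    for y1 in range(n1 + 1):
        for y2 in range(n2 + 1):
            t = Table2x2(y1, n1, y2, n2)
            grid[(y1, y2)] = [METHODS[m](t, alpha) for m in methods]
    probs = np.array([grid[(y1, y2)] for y1, y2 in counts])  # reps x methods
    rng = np.random.default_rng(None if scenario.seed is None else scenario.seed + 1)
    # realize randomized decisions (deterministic rules have prob in {0,1})
    rejects = rng.random(probs.shape) < probs
    degenerate = int(np.sum((counts.sum(axis=1) == 0) | (counts.sum(axis=1) == n1 + n2)))
    props = {m: float(rejects[:, j].mean()) for j, m in enumerate(methods)}
    return SimulationResult(
        scenario=scenario, proportions=props, reps=scenario.reps, degenerate=degenerate
    )


def interval_noncoverage(
    scenario: Scenario,
    k_levels: Sequence[float] = (6.8, 8.0, 32.0),
    which: str = "conditional",
) -> SimulationResult:
    """Proportion of replicates whose 1/k support interval misses the true psi.

    Intervals with an infinite endpoint cover whenever the true value lies on
    the infinite side; degenerate replicates (y+ = 0 or n+) have a likelihood
    flat in psi, interval the whole line, and always cover.
    """
    psi_true = scenario.psi
    if not math.isfinite(psi_true):
        raise ValueError("interval coverage requires interior pi1, pi2 (finite true psi)")
    counts = _generate_counts(scenario)
    n1, n2 = scenario.n1, scenario.n2
    cover_grid: dict[tuple[int, int], list[bool]] = {}
    for y1 in range(n1 + 1):
        for y2 in range(n2 + 1):
            t = Table2x2(y1, n1, y2, n2)
            if t.y_plus == 0 or t.y_plus == t.n_plus:
                cover_grid[(y1, y2)] = [True] * len(k_levels)
                continue
            cover_grid[(y1, y2)] = [
                evidence.support_interval(t, k, which).covers(psi_true) for k in k_levels
            ]
    covered = np.array([cover_grid[(y1, y2)] for y1, y2 in counts])
    degenerate = int(np.sum((counts.sum(axis=1) == 0) | (counts.sum(axis=1) == n1 + n2)))
    props = {
        f"si_1_over_{k:g}": float(1.0 - covered[:, j].mean()) for j, k in enumerate(k_levels)
    }
    return SimulationResult(
        scenario=scenario, proportions=props, reps=scenario.reps, degenerate=degenerate
    )
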