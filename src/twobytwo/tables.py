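"""Core 2x2 table representation, parameterizations, and sample-space enumeration.

A 2x2 table arising from two independent binomial samples is summarised by
``(y1, n1, y2, n2)``: ``y1`` successes out of ``n1`` subjects in group 1 and
``y2`` out of ``n2`` in group 2.  The parameter of interest throughout the
package is the log odds ratio

    psi = logit(pi1) - logit(pi2),

with the nuisance parameter expressed either canonically as
``lambda = logit(pi2)`` or orthogonally as the marginal success probability
``lambda* = (n1*pi1 + n2*pi2) / (n1 + n2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

__all__ = [
    "Table2x2",
    "ParamPoint",
    "SampleSpace",
    "psi_hat_unconditional",
    "enumerate_sample_space",
]


@dataclass(frozen=True)
class Table2x2:
    """Observed counts of a 2x2 table with both group sizes fixed by design.

    Parameters
    ----------
    y1, y2
        Success counts in groups 1 and 2.
    n1, n2
        Group sizes (row totals).
    """

    y1: int
    n1: int
    y2: int
    n2: int

    def __post_init__(self) -> None:
        for name in ("y1", "n1", "y2", "n2"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)):
                raise TypeError(f"{name} must be an integer, got {v!r}")
            object.__setattr__(self, name, int(v))
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("group sizes n1, n2 must be >= 1")
        if not 0 <= self.y1 <= self.n1:
            raise ValueError(f"y1={self.y1} out of range [0, {self.n1}]")
        if not 0 <= self.y2 <= self.n2:
            raise ValueError(f"y2={self.y2} out of range [0, {self.n2}]")

    @property
    def y_plus(self) -> int:
        """Total number of successes."""
        return self.y1 + self.y2

    @property
    def n_plus(self) -> int:
        """Total number of subjects."""
        return self.n1 + self.n2

    @classmethod
    def from_cells(cls, a: int, b: int, c: int, d: int) -> "Table2x2":
        """Build from the four cells in row-major layout.

        ``a`` = successes group 1, ``b`` = failures group 1,
        ``c`` = successes group 2, ``d`` = failures group 2.
        """
        return cls(y1=a, n1=a + b, y2=c, n2=c + d)

    def cells(self) -> tuple[int, int, int, int]:
        """Return the (a, b, c, d) cell layout."""
        return self.y1, self.n1 - self.y1, self.y2, self.n2 - self.y2

    def conditioned_support(self) -> range:
        """Values y1 can take once the success total y+ is fixed."""
        lo = max(0, self.y_plus - self.n2)
        hi = min(self.n1, self.y_plus)
        return range(lo, hi + 1)

    def __str__(self) -> str:
        a, b, c, d = self.cells()
        return f"Table2x2(y1={self.y1}/{self.n1}, y2={self.y2}/{self.n2}; cells [{a} {b}; {c} {d}])"


def psi_hat_unconditional(table: Table2x2) -> float:
    """Unconditional MLE of the log odds ratio.

    ``exp(psi_hat) = [y1/(n1-y1)] / [y2/(n2-y2)]``.  Returns ``-inf`` /
    ``+inf`` when exactly one of the two cross-product terms sits at a
    boundary, and ``nan`` (undefined, a 0/0 form) when both do — e.g. when
    every subject failed or every subject succeeded.
    """
    num = table.y1 * (table.n2 - table.y2)  # zero -> OR estimate 0
    den = (table.n1 - table.y1) * table.y2  # zero -> OR estimate +inf
    if num == 0 and den == 0:
        return math.nan
    if num == 0:
        return -math.inf
    if den == 0:
        return math.inf
    return math.log(num / den)


@dataclass(frozen=True)
class ParamPoint:
    """One point of the dual-binomial parameter space, in all parameterizations.

    Stores the success probabilities ``(pi1, pi2)``, the log odds ratio
    ``psi``, the canonical nuisance ``lambda_can = logit(pi2)`` and the
    orthogonal nuisance ``lambda_star`` (the marginal success probability,
    which depends on the group sizes used to construct the point).
    """

    pi1: float
    pi2: float
    psi: float
    lambda_can: float
    lambda_star: float
    n1: int
    n2: int

    @classmethod
    def from_probs(cls, pi1: float, pi2: float, n1: int, n2: int) -> "ParamPoint":
        """Boundary probabilities (0 or 1) are allowed; psi/lambda then take
        extended-real values and only pmf evaluation remains meaningful."""
        if not (0.0 <= pi1 <= 1.0 and 0.0 <= pi2 <= 1.0):
            raise ValueError("pi1, pi2 must lie in [0, 1]")
        with np.errstate(divide="ignore", invalid="ignore"):
            psi = float(logit(pi1) - logit(pi2))
        with np.errstate(divide="ignore"):
            lam = float(logit(pi2))
        return cls(
            pi1=float(pi1),
            pi2=float(pi2),
            psi=psi,
            lambda_can=lam,
            lambda_star=(n1 * pi1 + n2 * pi2) / (n1 + n2),
            n1=n1,
            n2=n2,
        )

    @classmethod
    def from_canonical(cls, psi: float, lambda_can: float, n1: int, n2: int) -> "ParamPoint":
        if not math.isfinite(psi) or not math.isfinite(lambda_can):
            raise ValueError("psi and lambda_can must be finite")
        pi1 = float(expit(psi + lambda_can))
        pi2 = float(expit(lambda_can))
        return cls(
            pi1=pi1,
            pi2=pi2,
            psi=float(psi),
            lambda_can=float(lambda_can),
            lambda_star=(n1 * pi1 + n2 * pi2) / (n1 + n2),
            n1=n1,
            n2=n2,
        )

    @classmethod
    def from_orthogonal(cls, psi: float, lambda_star: float, n1: int, n2: int) -> "ParamPoint":
        """Invert (psi, lambda*) -> lambda by monotone root-finding.

        The map ``lambda -> (n1*expit(psi+lambda) + n2*expit(lambda))/n+`` is
        strictly increasing, so the root is unique; it is bracketed by
        expansion starting from [-50, 50] and solved to |residual| < 1e-12.
        """
        if not 0.0 < lambda_star < 1.0:
            raise ValueError("lambda_star must lie in the open interval (0, 1)")
        if not math.isfinite(psi):
            raise ValueError("psi must be finite to invert the orthogonal map")
        n_plus = n1 + n2

        def residual(lam: float) -> float:
            return (n1 * expit(psi + lam) + n2 * expit(lam)) / n_plus - lambda_star

        lo, hi = -50.0, 50.0
        while residual(lo) > 0:
            lo *= 2.0
        while residual(hi) < 0:
            hi *= 2.0
        lam = float(brentq(residual, lo, hi, xtol=1e-14, rtol=8.9e-16))
        return cls.from_canonical(psi, lam, n1, n2)


_PARAMETERIZATIONS = ("probs", "canonical", "orthogonal")


def convert(point: ParamPoint, n1: int, n2: int, target: str) -> ParamPoint:
    """Re-express a parameter point for group sizes (n1, n2).

    ``target`` names the coordinate pair taken as primitive: ``"probs"``
    for (pi1, pi2), ``"canonical"`` for (psi, lambda), ``"orthogonal"``
    for (psi, lambda*).  The returned point always carries all
    parameterizations; ``target`` selects which pair of the input is
    trusted when the group sizes change (lambda* is size-dependent).
    """
    if target not in _PARAMETERIZATIONS:
        raise ValueError(f"unknown parameterization {target!r}; expected one of {_PARAMETERIZATIONS}")
    if target == "probs":
        return ParamPoint.from_probs(point.pi1, point.pi2, n1, n2)
    if target == "canonical":
        return ParamPoint.from_canonical(point.psi, point.lambda_can, n1, n2)
    return ParamPoint.from_orthogonal(point.psi, point.lambda_star, n1, n2)


@dataclass(frozen=True)
class SampleSpace:
    """All table configurations compatible with the design.

    Unconditioned: every ``(y1, y2)`` with ``0<=y1<=n1``, ``0<=y2<=n2``
    ((n1+1)(n2+1) configurations).  Conditioned on the success total y+:
    ``y1`` runs over ``max(0, y+-n2) .. min(n1, y+)`` with ``y2 = y+ - y1``.
    Each configuration carries the per-table unconditional MLE of psi.
    """

    n1: int
    n2: int
    y_plus: Optional[int]
    configurations: tuple[tuple[int, int, float], ...] = field(repr=False)

    @property
    def conditioned(self) -> bool:
        return self.y_plus is not None

    def __len__(self) -> int:
        return len(self.configurations)

    def __iter__(self) -> Iterator[tuple[int, int, float]]:
        return iter(self.configurations)

    def tables(self) -> Iterator[Table2x2]:
        for y1, y2, _ in self.configurations:
            yield Table2x2(y1=y1, n1=self.n1, y2=y2, n2=self.n2)

    def psi_tilde_values(self) -> list[float]:
        """Per-configuration MLEs of psi (extended reals, nan = undefined)."""
        return [p for _, _, p in self.configurations]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.configurations, columns=["y1", "y2", "psi_tilde"])

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def enumerate_sample_space(n1: int, n2: int, y_plus: Optional[int] = None) -> SampleSpace:
    """Enumerate every table configuration, optionally conditioning on y+."""
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    configs: list[tuple[int, int, float]] = []
    if y_plus is None:
        for y1 in range(n1 + 1):
            for y2 in range(n2 + 1):
                configs.append((y1, y2, psi_hat_unconditional(Table2x2(y1, n1, y2, n2))))
    else:
        if not 0 <= y_plus <= n1 + n2:
            raise ValueError(f"y_plus={y_plus} out of range [0, {n1 + n2}]")
        for y1 in range(max(0, y_plus - n2), min(n1, y_plus) + 1):
            y2 = y_plus - y1
            configs.append((y1, y2, psi_hat_unconditional(Table2x2(y1, n1, y2, n2))))
    return SampleSpace(n1=n1, n2=n2, y_plus=y_plus, configurations=tuple(configs))
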