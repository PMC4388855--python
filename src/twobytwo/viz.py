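"""Likelihood-surface and standardized-evidence plots.

All numbers plotted here come from :mod:`twobytwo.likelihoods` and
:mod:`twobytwo.evidence`; this module only arranges them.  Surfaces are
drawn over the orthogonal parameterization (psi, lambda*), in which the
full-likelihood contours are nearly axis-aligned and the near-flatness of
the marginal likelihood of y+ in psi is visible directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from . import evidence
from .likelihoods import (
    LikelihoodCurve,
    conditional_mle,
    likelihood_curve,
    loglik_full_canonical,
    loglik_marginal,
)
from .tables import ParamPoint, Table2x2

__all__ = ["SurfaceGrid", "surface", "cross_sections", "evidence_plot"]


@dataclass(frozen=True)
class SurfaceGrid:
    """Standardized likelihood values over a (psi, lambda*) grid."""

    kind: str  # "full" | "marginal"
    psi: np.ndarray
    lambda_star: np.ndarray
    values: np.ndarray  # shape (len(lambda_star), len(psi)), max 1

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.lambda_star), len(self.psi)):
            raise ValueError("values shape must be (len(lambda_star), len(psi))")

    def to_dataframe(self):
        import pandas as pd

        psi, lam = np.meshgrid(self.psi, self.lambda_star)
        return pd.DataFrame(
            {"psi": psi.ravel(), "lambda_star": lam.ravel(), "value": self.values.ravel()}
        )


def _loglik_on_grid(table: Table2x2, kind: str, psi: np.ndarray, lam_star: np.ndarray) -> np.ndarray:
    out = np.empty((len(lam_star), len(psi)))
    for i, ls in enumerate(lam_star):
        for j, p in enumerate(psi):
            pt = ParamPoint.from_orthogonal(float(p), float(ls), table.n1, table.n2)
            if kind == "full":
                out[i, j] = loglik_full_canonical(table, pt.psi, pt.lambda_can)
            else:
                out[i, j] = loglik_marginal(table.y_plus, table.n1, table.n2, pt)
    return out


def surface(
    table: Table2x2,
    kind: str = "full",
    psi_range: tuple[float, float] = (-10.0, 10.0),
    lambda_star_range: tuple[float, float] = (0.02, 0.98),
    resolution: int = 201,
) -> SurfaceGrid:
    """Standardized full or marginal likelihood surface over (psi, lambda*)."""
    if kind not in ("full", "marginal"):
        raise ValueError("kind must be 'full' or 'marginal'")
    if resolution < 21:
        raise ValueError("resolution must be at least 21 per axis")
    lo, hi = lambda_star_range
    if not (0.0 < lo < hi < 1.0):
        raise ValueError("lambda_star range must be interior to (0, 1)")
    psi = np.linspace(*psi_range, resolution)
    lam_star = np.linspace(lo, hi, resolution)
    ll = _loglik_on_grid(table, kind, psi, lam_star)
    return SurfaceGrid(kind=kind, psi=psi, lambda_star=lam_star, values=np.exp(ll - ll.max()))


def cross_sections(
    table: Table2x2,
    kind: str = "full",
    lambda_star_values: Sequence[float] = (0.1, 0.3, 0.5, 0.7, 0.9),
    psi_grid: Optional[np.ndarray] = None,
) -> list[LikelihoodCurve]:
    """Likelihood-vs-psi slices at fixed lambda* values, plus an overlay.

    For the full likelihood the overlay is the profile curve (the pointwise
    upper envelope of all slices); for the marginal likelihood it is the
    conditional curve, which does not depend on lambda* at all.
    """
    if kind not in ("full", "marginal"):
        raise ValueError("kind must be 'full' or 'marginal'")
    if psi_grid is None:
        center = conditional_mle(table)
        if not math.isfinite(center):
            center = 0.0
        psi_grid = np.linspace(max(-12.0, center - 8.0), min(12.0, center + 8.0), 401)
    psi_grid = np.asarray(psi_grid, dtype=float)
    curves = []
    for ls in lambda_star_values:
        if not 0.0 < ls < 1.0:
            raise ValueError("lambda* values must be interior to (0, 1)")
        ll = _loglik_on_grid(table, kind, psi_grid, np.array([ls]))[0]
        curves.append(
            LikelihoodCurve(kind=f"{kind}_section_lambda_star={ls:g}", psi=psi_grid, loglik=ll)
        )
    overlay_kind = "profile" if kind == "full" else "conditional"
    curves.append(likelihood_curve(table, overlay_kind, psi_grid=psi_grid))
    return curves


def plot_surface(grid: SurfaceGrid, path=None, cmap: str = "YlOrRd_r", levels: int = 15):
    """Filled contour plot of a likelihood surface (monotone colormap)."""
    fig, ax = plt.subplots(figsize=(6, 5))
    cs = ax.contourf(grid.psi, grid.lambda_star, grid.values, levels=levels, cmap=cmap)
    fig.colorbar(cs, ax=ax, label="standardized likelihood")
    ax.set_xlabel(r"$\psi$ (log odds ratio)")
    ax.set_ylabel(r"$\lambda^*$ (marginal success probability)")
    ax.set_title(f"{grid.kind} likelihood")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def evidence_plot(
    table: Table2x2,
    k_levels: Sequence[float] = (6.8, 8.0, 32.0),
    which: Sequence[str] = ("conditional", "profile", "modified_profile"),
    path=None,
    psi_grid: Optional[np.ndarray] = None,
) -> tuple[object, dict[str, LikelihoodCurve]]:
    """Standardized likelihood curves with 1/k support-interval rulers.

    Returns the figure and the underlying curves keyed by likelihood kind,
    so the plotted numbers can be checked against the evidence module.
    """
    curves = {w: likelihood_curve(table, w, psi_grid=psi_grid) for w in which}
    fig, ax = plt.subplots(figsize=(6.5, 4.5))
    styles = {"conditional": "-", "profile": "--", "modified_profile": ":"}
    for w, curve in curves.items():
        ax.plot(curve.psi, curve.standardized, styles.get(w, "-"), label=w)
    for k in k_levels:
        ax.axhline(1.0 / k, color="grey", lw=0.8)
        ax.annotate(f"1/{k:g}", xy=(ax.get_xlim()[1], 1.0 / k), fontsize=8, ha="right")
    mle = conditional_mle(table)
    if math.isfinite(mle):
        ax.axvline(mle, color="k", lw=0.6, ls="--")
        ax.annotate(f"$\\hat\\psi$ = {mle:.2f}", xy=(mle, 1.02), ha="center", fontsize=9)
    ax.set_xlabel(r"$\psi$ (log odds ratio)")
    ax.set_ylabel("standardized likelihood")
    ax.set_ylim(0, 1.08)
    ax.legend(loc="upper right", fontsize=8)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig, curves
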