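"""Qualitative bias plots: equimolar response pairs with a centered
quadratic fit.

For each compound the normalized AUC response in the βarr2 assay (x) is
paired with the response in the miniGαq assay (y) at the same concentration
(per-concentration means over wells and experiments, with SEM error bars),
and a centered second-order polynomial

    y = a + b·(x − x̄) + c·(x − x̄)²

is fitted by ordinary least squares.  A compound whose curve runs below the
reference agonist's curve at matched x preferentially recruits β-arrestin-2.
The plotting layer is a thin rendering of these numeric series; analyses
and tests target the series, not images.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .types import AUCResponse, PipelineOrderError, group_by


@dataclass(frozen=True)
class PairedPoint:
    concentration: float
    x: float  # βarr2 normalized AUC, % of reference max
    y: float  # miniGαq normalized AUC, %
    x_sem: float
    y_sem: float


@dataclass
class BiasPlotSeries:
    compound: str
    points: list[PairedPoint]
    quad_coeffs: tuple[float, float, float]  # (a, b, c)
    x_center: float

    def predict(self, x: np.ndarray) -> np.ndarray:
        a, b, c = self.quad_coeffs
        dx = np.asarray(x, dtype=float) - self.x_center
        return a + b * dx + c * dx**2


def _mean_sem(values: list[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    sem = float(np.std(arr, ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
    return float(np.mean(arr)), sem


def pair_equimolar(
    responses_arr2: Sequence[AUCResponse], responses_gq: Sequence[AUCResponse]
) -> list[PairedPoint]:
    """Pair per-concentration mean responses of the two assays.

    Requires at least 3 concentrations shared between the assays; raises
    ``ValueError`` otherwise.
    """
    for r in list(responses_arr2) + list(responses_gq):
        if r.response_normalized is None:
            raise PipelineOrderError("responses must be normalized before pairing")
    by_conc_a = group_by(responses_arr2, lambda r: r.annotation.concentration)
    by_conc_g = group_by(responses_gq, lambda r: r.annotation.concentration)
    shared = sorted(set(by_conc_a) & set(by_conc_g))
    if len(shared) < 3:
        raise ValueError(
            f"need >= 3 shared concentrations between assays, got {len(shared)}"
        )
    points = []
    for conc in shared:
        x, x_sem = _mean_sem([r.response_normalized for r in by_conc_a[conc]])
        y, y_sem = _mean_sem([r.response_normalized for r in by_conc_g[conc]])
        points.append(PairedPoint(conc, x, y, x_sem, y_sem))
    return points


def fit_centered_quadratic(
    points: Sequence[PairedPoint],
) -> tuple[tuple[float, float, float], float]:
    """OLS fit of y = a + b·(x − x̄) + c·(x − x̄)² to the paired points.

    Returns ((a, b, c), x̄).  Raises ``ValueError`` for fewer than 3 points
    or a rank-deficient design (e.g. all x equal).
    """
    if len(points) < 3:
        raise ValueError(f"need >= 3 points for a quadratic fit, got {len(points)}")
    x = np.array([p.x for p in points], dtype=float)
    y = np.array([p.y for p in points], dtype=float)
    x_center = float(np.mean(x))
    dx = x - x_center
    design = np.column_stack([np.ones_like(dx), dx, dx**2])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("rank-deficient quadratic design (degenerate x values)")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return (float(coef[0]), float(coef[1]), float(coef[2])), x_center


def build_series(
    compound: str,
    responses_arr2: Sequence[AUCResponse],
    responses_gq: Sequence[AUCResponse],
) -> BiasPlotSeries:
    points = pair_equimolar(responses_arr2, responses_gq)
    coeffs, x_center = fit_centered_quadratic(points)
    return BiasPlotSeries(compound, points, coeffs, x_center)


def plot_series(
    series_list: Sequence[BiasPlotSeries],
    reference: str,
    path: str,
) -> None:
    """Render one panel per compound (compound curve vs reference curve)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ref = next((s for s in series_list if s.compound == reference), None)
    others = [s for s in series_list if s.compound != reference]
    n = max(len(others), 1)
    ncol = min(n, 3)
    nrow = (n + ncol - 1) // ncol
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3.5 * nrow), squeeze=False)
    for ax, s in zip(axes.flat, others or series_list):
        for curve, color in ((s, "tab:red"), (ref, "black")):
            if curve is None:
                continue
            xs = np.array([p.x for p in curve.points])
            ys = np.array([p.y for p in curve.points])
            ax.errorbar(
                xs, ys,
                xerr=[p.x_sem for p in curve.points],
                yerr=[p.y_sem for p in curve.points],
                fmt="o", ms=3, color=color, alpha=0.7,
            )
            grid = np.linspace(xs.min(), xs.max(), 100)
            ax.plot(grid, curve.predict(grid), color=color,
                    label=curve.compound)
        ax.set_xlabel("βarr2 response (% ref max)")
        ax.set_ylabel("miniGαq response (% ref max)")
        ax.set_title(s.compound)
        ax.legend(fontsize=8)
    for ax in axes.flat[len(others or series_list):]:
        ax.set_visible(False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
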