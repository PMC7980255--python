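"""End-to-end orchestration: curves → regime fits → λ* → condition comparison.

A batch of localization datasets (optionally ROI-masked, optionally grouped
into named conditions) is turned into curves, each curve is fitted according
to a declarative fit plan, and for every exponential fit the decay length is
normalized by the cluster density measured at the start of its window. The
report aggregates per-condition means ± sd and supports two-sample t tests
between conditions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .clusters import cluster_density, clusters_at_scale
from .curves import EpsilonGrid, SuperStructureCurve, superstructure_curve
from .locio import CircleROI, LocalizationTable, PolygonROI
from .models import fit_regime, normalize_lambda, scan_window

logger = logging.getLogger("superstruct")

__all__ = ["FitStep", "DatasetResult", "AnalysisReport", "run_curve_pipeline",
           "compare_conditions"]

DEFAULT_MIN_CLUSTER_SIZE = 30


@dataclass(frozen=True)
class FitStep:
    """One entry of a fit plan.

    Either a fixed ``window`` (ε_lo, ε_hi) or a ``scan`` search range (with
    ``min_points``) must be given. For exponential steps the cluster density
    is measured at the window's lower edge and λ* is reported.
    """

    model_kind: str
    window: tuple[float, float] | None = None
    scan: tuple[float, float] | None = None
    min_points: int = 5
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE

    def __post_init__(self) -> None:
        if (self.window is None) == (self.scan is None):
            raise ValueError("exactly one of window/scan must be set")


@dataclass
class DatasetResult:
    name: str
    condition: str
    curve: SuperStructureCurve | None
    fits: list = field(default_factory=list)
    quantities: dict[str, float] = field(default_factory=dict)
    error: str | None = None


@dataclass
class AnalysisReport:
    datasets: list[DatasetResult]
    conditions: dict[str, dict[str, tuple[float, float, int]]]
    # condition -> quantity -> (mean, sd, n)

    def values(self, condition: str, quantity: str) -> np.ndarray:
        vals = [
            d.quantities[quantity]
            for d in self.datasets
            if d.condition == condition and quantity in d.quantities
        ]
        return np.asarray(vals, dtype=float)


def _density_roi(table: LocalizationTable, radius_um: float) -> CircleROI:
    """Circular ROI centered on the data's bounding-box center."""
    xy = table.xy
    cx, cy = (xy.min(axis=0) + xy.max(axis=0)) / 2.0
    return CircleROI(cx, cy, radius_um * 1000.0)


def run_curve_pipeline(
    inputs: Sequence[tuple[str, LocalizationTable, CircleROI | PolygonROI | None, str]],
    grid: EpsilonGrid,
    fit_plan: Sequence[FitStep],
    density_roi_radius_um: float = 1.5,
) -> AnalysisReport:
    """Run curves and fits for a batch of datasets.

    ``inputs`` is a sequence of (name, table, roi-or-None, condition). Per
    dataset: the table is ROI-masked, the curve computed with the EMST
    engine, and each fit step applied. Exponential steps additionally
    measure the cluster density ρcl — via a fixed-ε cluster analysis at the
    window start inside a circular region of ``density_roi_radius_um`` — and
    report λ* = λ·√ρcl. A failing dataset is recorded with its error and the
    batch continues. Per-condition means ± sample sd are aggregated over
    datasets.
    """
    from .locio import apply_roi

    results: list[DatasetResult] = []
    for name, table, roi, condition in inputs:
        res = DatasetResult(name=name, condition=condition, curve=None)
        results.append(res)
        try:
            masked = apply_roi(table, roi) if roi is not None else table
            if len(masked) == 0:
                raise ValueError("ROI mask removed all localizations")
            curve = superstructure_curve(masked, grid, nmin=0, engine="mst")
            res.curve = curve
            for step in fit_plan:
                if step.window is not None:
                    fit = fit_regime(curve, step.window, step.model_kind)
                    window = step.window
                else:
                    window, fit = scan_window(
                        curve, step.model_kind, step.min_points, step.scan
                    )
                res.fits.append(fit)
                logger.info(
                    "%s: %s fit on window %s -> %s (red chi2 %.3g)",
                    name, step.model_kind, window, fit.params, fit.reduced_chi2,
                )
                if step.model_kind == "exponential":
                    lam = fit.params["lam"]
                    res.quantities["lam"] = lam
                    cs = clusters_at_scale(
                        masked, window[0], step.min_cluster_size
                    )
                    droi = _density_roi(masked, density_roi_radius_um)
                    dens = cluster_density(cs, droi)
                    if dens.density_um2 > 0:
                        res.quantities["rho_cl"] = dens.density_um2
                        res.quantities["lam_star"] = normalize_lambda(
                            lam, dens.density_um2
                        ).lam_star
                elif step.model_kind == "poisson_intra":
                    res.quantities["rho_em"] = fit.params["rho_em"]
                elif step.model_kind == "poisson_cluster":
                    res.quantities["rho_cl_fit"] = fit.params["rho_cl"]
        except (ValueError, RuntimeError) as exc:
            res.error = str(exc)
            logger.warning("%s: %s", name, exc)

    conditions: dict[str, dict[str, tuple[float, float, int]]] = {}
    names = sorted({r.condition for r in results})
    quantities = sorted({q for r in results for q in r.quantities})
    for cond in names:
        summary: dict[str, tuple[float, float, int]] = {}
        for q in quantities:
            vals = [
                r.quantities[q] for r in results
                if r.condition == cond and q in r.quantities
            ]
            if vals:
                arr = np.asarray(vals)
                sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
                summary[q] = (float(arr.mean()), sd, len(arr))
        conditions[cond] = summary
    return AnalysisReport(datasets=results, conditions=conditions)


def compare_conditions(
    report: AnalysisReport,
    condition_a: str,
    condition_b: str,
    quantity: str,
    welch: bool = False,
) -> dict[str, float]:
    """Two-sample t test on a per-dataset quantity between two conditions.

    Uses the pooled-variance Student variant by default; ``welch=True``
    switches to the unequal-variance form.
    """
    a = report.values(condition_a, quantity)
    b = report.values(condition_b, quantity)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"need at least 2 datasets per condition for {quantity!r} "
            f"(got {len(a)} and {len(b)})"
        )
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    if math.isnan(t):  # identical, zero-variance samples
        t, p = 0.0, 1.0
    return {"t": float(t), "p": float(p), "n_a": len(a), "n_b": len(b)}
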