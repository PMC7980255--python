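"""Regime models for Nc(ε) curves: Poisson avoidance decays and exponentials.

Three functional forms describe how the normalized cluster count decays as
the neighborhood radius grows:

* **Intra-cluster Poisson** — at ε below the cluster size, points merge at a
  rate set by the emitter density ρem inside clusters. Writing
  x = π·ρem·ε², the normalized count is Σ_{k=0..m} x^k / ((k+1)·k!) · e^(−x):
  the probability of finding at most m other emitters in the ε-disc, with
  each k-term divided by k+1 so a cluster of k+1 mutually-neighboring points
  is counted once. The default truncation is m = 2.
* **Cluster-level Poisson** — when whole clusters merge purely by random
  proximity (no connectivity), the same form applies with the cluster
  density ρcl in place of ρem, a free prefactor f, and m = 1.
* **Exponential** — when clusters are bridged by sparse connection points,
  the super-cluster regime decays as g·e^(−ε/λ); the decay length λ
  quantifies connectivity (smaller λ = stronger connectivity).

The intra-cluster regime ends near ε* = 3/√(π·ρem) (three decay lengths of
the avoidance function, ~99% merged). λ mixes connectivity with cluster
density as λ ~ ρcl^(−1/2); the dimensionless λ* = λ·√ρcl isolates the
connectivity contribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import optimize

from .curves import CurveEnsemble, SuperStructureCurve

__all__ = [
    "RegimeModelFit",
    "NormalizedDecay",
    "eval_poisson_intra",
    "eval_poisson_cluster",
    "eval_exponential",
    "epsilon_star",
    "fit_regime",
    "fit_ensemble",
    "scan_window",
    "classify_regime",
    "normalize_lambda",
]

ModelKind = Literal["poisson_intra", "poisson_cluster", "exponential"]

#: Grid points with fewer clusters than this are excluded from fit windows
#: (counting noise dominates the log-scale tail below it).
NC_FLOOR = 5

_UM2_TO_NM2 = 1e-6  # ρ [μm⁻²] → ρ [nm⁻²]


@dataclass(frozen=True)
class RegimeModelFit:
    """A fitted regime model over a stated ε window."""

    model_kind: ModelKind
    window: tuple[float, float]
    params: dict[str, float]
    chi2: float
    r2: float
    n_points: int

    @property
    def reduced_chi2(self) -> float:
        dof = self.n_points - len(self.params)
        return self.chi2 / dof if dof > 0 else math.inf


@dataclass(frozen=True)
class NormalizedDecay:
    """Decay length λ normalized by the mean inter-cluster spacing.

    λ* = (λ in μm) · √(ρcl in μm⁻²), dimensionless.
    """

    lam: float
    rho_cl: float
    lam_star: float


def _poisson_series(x: np.ndarray, m: int) -> np.ndarray:
    """Σ_{k=0..m} x^k / ((k+1)·k!) · e^(−x), the truncated avoidance series."""
    x = np.asarray(x, dtype=float)
    total = np.zeros_like(x)
    for k in range(m + 1):
        total += x**k / ((k + 1) * math.factorial(k))
    return total * np.exp(-x)


def eval_poisson_intra(
    epsilon: np.ndarray | float, rho_em: float, m: int = 2
) -> np.ndarray | float:
    """Intra-cluster Poisson avoidance model; ε in nm, ρem in μm⁻².

    Equals 1 exactly at ε = 0 for any m and ρem.
    """
    if rho_em <= 0:
        raise ValueError("rho_em must be positive")
    if m < 0:
        raise ValueError("m must be non-negative")
    eps = np.asarray(epsilon, dtype=float)
    if np.any(eps < 0):
        raise ValueError("epsilon must be non-negative")
    x = math.pi * rho_em * _UM2_TO_NM2 * eps**2
    out = _poisson_series(x, m)
    return float(out) if np.isscalar(epsilon) else out


def eval_poisson_cluster(
    epsilon: np.ndarray | float, rho_cl: float, f: float, m: int = 1
) -> np.ndarray | float:
    """Cluster-level Poisson model with prefactor f; ρcl in μm⁻²."""
    if rho_cl <= 0:
        raise ValueError("rho_cl must be positive")
    if f <= 0:
        raise ValueError("f must be positive")
    eps = np.asarray(epsilon, dtype=float)
    if np.any(eps < 0):
        raise ValueError("epsilon must be non-negative")
    x = math.pi * rho_cl * _UM2_TO_NM2 * eps**2
    out = f * _poisson_series(x, m)
    return float(out) if np.isscalar(epsilon) else out


def eval_exponential(
    epsilon: np.ndarray | float, g: float, lam: float
) -> np.ndarray | float:
    """Exponential super-cluster model g·e^(−ε/λ); λ in nm."""
    if g <= 0:
        raise ValueError("g must be positive")
    if lam <= 0:
        raise ValueError("lam must be positive")
    eps = np.asarray(epsilon, dtype=float)
    out = g * np.exp(-eps / lam)
    return float(out) if np.isscalar(epsilon) else out


def epsilon_star(rho_em: float) -> float:
    """Upper ε limit of the intra-cluster regime, 3/√(π·ρem), in nm.

    ρem is in μm⁻². Equivalent to 3·Rcl/√Nem when ρem = Nem/(π·Rcl²).
    """
    if rho_em <= 0:
        raise ValueError("rho_em must be positive")
    return 3.0 / math.sqrt(math.pi * rho_em * _UM2_TO_NM2)


def _fit_exponential_log(
    eps: np.ndarray, y: np.ndarray, weights: np.ndarray, window
) -> tuple[float, float]:
    """WLS of ln(y) on ε; returns (g, λ). Raises if the slope is non-decaying."""
    w = np.asarray(weights, dtype=float)
    design = np.column_stack([np.ones_like(eps), eps])
    coef, *_ = np.linalg.lstsq(design * w[:, None], w * np.log(y), rcond=None)
    intercept, slope = coef
    if slope >= 0:
        raise RuntimeError(
            f"exponential fit in window {window} gave non-decaying slope {slope:.3g}"
        )
    return math.exp(intercept), -1.0 / slope


def _window_slice(
    curve: SuperStructureCurve, window: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = window
    if lo >= hi:
        raise ValueError("fit window must satisfy lo < hi")
    eps = curve.grid.values
    mask = (eps >= lo) & (eps <= hi) & (curve.nc >= NC_FLOOR)
    return eps[mask], curve.normalized[mask]


def fit_regime(
    curve: SuperStructureCurve,
    window: tuple[float, float],
    model_kind: ModelKind,
    m: int | None = None,
    weights: np.ndarray | None = None,
) -> RegimeModelFit:
    """Least-squares fit of one regime model to the normalized curve.

    The curve is restricted to grid points inside the closed ε window; grid
    points with Nc below the counting-noise floor are excluded. Exponential
    fits are done as weighted linear regression of ln(Nc/Nloc) on ε with
    inverse-variance weights from Poisson counting noise on the cluster
    count (sd of ln Nc ≈ 1/√Nc, so point weights ∝ √Nc); Poisson fits by
    bounded nonlinear least squares initialized from the log-slope of the
    first two window points. χ² uses unit weights on the normalized values
    unless per-point weights (e.g. ensemble sd) are given.
    """
    eps, y = _window_slice(curve, window)
    return _fit_window_data(
        eps, y, y * curve.nloc, model_kind, m, weights, window
    )


def fit_ensemble(
    ensemble: CurveEnsemble,
    nloc_mean: float,
    window: tuple[float, float],
    model_kind: ModelKind,
    m: int | None = None,
) -> RegimeModelFit:
    """Fit a regime model to the mean normalized curve of an ensemble.

    ``nloc_mean`` (the mean localization count of the member curves) sets
    the counting-noise floor and the exponential-fit weights, exactly as for
    a single curve.
    """
    lo, hi = window
    eps = ensemble.grid.values
    counts = ensemble.mean * nloc_mean
    mask = (eps >= lo) & (eps <= hi) & (counts >= NC_FLOOR)
    return _fit_window_data(
        eps[mask], ensemble.mean[mask], counts[mask], model_kind, m, None, window
    )


def _fit_window_data(
    eps: np.ndarray,
    y: np.ndarray,
    counts: np.ndarray,
    model_kind: ModelKind,
    m: int | None,
    weights: np.ndarray | None,
    window: tuple[float, float],
) -> RegimeModelFit:
    if len(eps) < 4:
        raise ValueError(
            f"need at least 4 usable grid points in window {window}, got {len(eps)}"
        )
    if np.any(y <= 0):
        raise ValueError("normalized values in the fit window must be positive")

    if model_kind == "exponential":
        g, lam = _fit_exponential_log(eps, y, np.sqrt(counts), window)
        params = {"g": g, "lam": lam}
        pred = eval_exponential(eps, g, lam)
    else:
        # initial density from the avoidance-function log-slope of the first
        # two points: ln(y1/y0) ≈ −πρ(ε1² − ε0²)
        de2 = eps[1] ** 2 - eps[0] ** 2
        with np.errstate(divide="ignore"):
            rho0 = -math.log(y[1] / y[0]) / (math.pi * de2) / _UM2_TO_NM2
        if not np.isfinite(rho0) or rho0 <= 0:
            rho0 = 1.0 / (math.pi * _UM2_TO_NM2 * max(eps[-1], 1.0) ** 2)
        if model_kind == "poisson_intra":
            mm = 2 if m is None else m

            def f_model(e, rho):
                return eval_poisson_intra(e, rho, mm)

            p0, bounds = [rho0], ([1e-12], [np.inf])
        elif model_kind == "poisson_cluster":
            mm = 1 if m is None else m

            def f_model(e, rho, f):
                return eval_poisson_cluster(e, rho, f, mm)

            p0, bounds = [rho0, float(y[0])], ([1e-12, 1e-12], [np.inf, np.inf])
        else:
            raise ValueError(f"unknown model kind {model_kind!r}")
        try:
            popt, _ = optimize.curve_fit(
                f_model, eps, y, p0=p0, bounds=bounds,
                sigma=weights, maxfev=20000,
            )
        except RuntimeError as exc:
            raise RuntimeError(
                f"{model_kind} fit did not converge in window {window} "
                f"(initial guess {p0})"
            ) from exc
        if model_kind == "poisson_intra":
            params = {"rho_em": float(popt[0])}
        else:
            params = {"rho_cl": float(popt[0]), "f": float(popt[1])}
        pred = f_model(eps, *popt)

    resid = y - pred
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        chi2 = float(np.sum((resid / np.where(w > 0, w, 1.0)) ** 2))
    else:
        chi2 = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return RegimeModelFit(
        model_kind=model_kind,
        window=(float(window[0]), float(window[1])),
        params=params,
        chi2=chi2,
        r2=r2,
        n_points=len(eps),
    )


def scan_window(
    curve: SuperStructureCurve,
    model_kind: ModelKind,
    min_points: int,
    search_range: tuple[float, float],
) -> tuple[tuple[float, float], RegimeModelFit]:
    """Grid search for the best-fit contiguous window inside a search range.

    All contiguous windows of at least ``min_points`` grid points are fitted
    and the one minimizing reduced χ² is returned. Windows whose reduced χ²
    is within 5% (plus a 10⁻¹² absolute floor for numerically exact fits) of
    the minimum are treated as tied; ties resolve deterministically to the
    widest window, then the smallest lower edge, so the longest regime
    consistent with the best goodness of fit is reported.
    """
    if min_points < 4:
        raise ValueError("min_points must be at least 4")
    lo, hi = search_range
    eps = curve.grid.values
    idx = np.flatnonzero((eps >= lo) & (eps <= hi))
    if len(idx) < min_points:
        raise ValueError(
            f"search range {search_range} holds {len(idx)} grid points, "
            f"fewer than min_points={min_points}"
        )
    fits: list[tuple[tuple[float, float], RegimeModelFit]] = []
    for a in range(len(idx)):
        for b in range(a + min_points - 1, len(idx)):
            window = (float(eps[idx[a]]), float(eps[idx[b]]))
            try:
                fits.append((window, fit_regime(curve, window, model_kind)))
            except (ValueError, RuntimeError):
                continue
    if not fits:
        raise ValueError(f"no admissible fit window inside {search_range}")
    best_chi2 = min(f.reduced_chi2 for _, f in fits)
    threshold = best_chi2 * 1.05 + 1e-12
    tied = [(w, f) for w, f in fits if f.reduced_chi2 <= threshold]
    tied.sort(key=lambda wf: (-(wf[0][1] - wf[0][0]), wf[0][0]))
    return tied[0]


def classify_regime(
    curve: SuperStructureCurve, window: tuple[float, float]
) -> dict:
    """Decide whether a super-cluster window decays exponentially or Poissonian.

    Fits both the exponential and the cluster-level Poisson model on the
    window and reports the one with lower reduced χ². "exponential" signals
    connectivity between clusters; "poisson" signals unconnected clusters
    (or noise). Both fits are returned so the caller can judge the margin.
    """
    fit_exp = fit_regime(curve, window, "exponential")
    fit_poi = fit_regime(curve, window, "poisson_cluster")
    kind = (
        "exponential"
        if fit_exp.reduced_chi2 <= fit_poi.reduced_chi2
        else "poisson"
    )
    return {"kind": kind, "fits": {"exponential": fit_exp, "poisson": fit_poi}}


def normalize_lambda(lam: float, rho_cl: float) -> NormalizedDecay:
    """Remove the cluster-density contribution from a decay length.

    λ* = (λ/1000)·√ρcl with λ in nm and ρcl in μm⁻²; the mean inter-cluster
    spacing is ρcl^(−1/2), so λ* is λ in units of that spacing.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    if rho_cl <= 0:
        raise ValueError("rho_cl must be positive")
    return NormalizedDecay(
        lam=lam, rho_cl=rho_cl, lam_star=(lam / 1000.0) * math.sqrt(rho_cl)
    )
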