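"""Synthetic SMLM datasets of connected Gaussian clusters with ground truth.

The generator emulates interconnected protein clusters on a 2D plane:

1. ``Ncl`` cluster centers are placed uniformly in an L×L box (L in μm).
2. Each cluster holds ``Nem`` emitters drawn from an isotropic Gaussian of
   standard deviation σem about its center, so the effective cluster radius
   is Rcl = 2σem (95% of emitters) and the internal emitter density is
   ρem = Nem/(π·Rcl²).
3. Cluster pairs closer than ``b`` are eligible for a connection; each
   eligible pair is bridged independently with a per-pair probability scaled
   so the expected realized connectivity — drawn connections over all
   Ncl(Ncl−1)/2 pairs — matches the nominal ``pr``.
4. A connection places candidate sites every ``delta_conn`` (10 nm) strictly
   between the two centers; each site is occupied with probability
   ``prconn`` and jittered by an isotropic Gaussian of sd σconn.
5. Optional background noise is a homogeneous Poisson point process of
   intensity ρn over the box.

Defaults reproduce the standard conditions: L = 3.5 μm, Ncl = 100
(ρcl ≈ 8.2 μm⁻²), Nem = 80, σem = 20 nm (ρem ≈ 16,000 μm⁻²), b = 1 μm,
prconn = 0.5, no noise. Boundaries are open: emitters of edge clusters may
fall outside the box and are kept; area normalizations use L².
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .locio import LocalizationTable

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "simulate_dataset",
    "add_noise",
    "simulate_uniform_cluster",
    "replica_seeds",
]

NM_PER_UM = 1000.0


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the connected-cluster generator (lengths: see units)."""

    L: float = 3.5            # box side, μm
    n_clusters: int = 100     # Ncl
    n_emitters: int = 80      # Nem, emitters per cluster
    sigma_em: float = 20.0    # nm, cluster Gaussian sd
    b: float = 1.0            # μm, max center distance for a connection
    pr_nominal: float = 0.0   # target connectivity fraction over all pairs
    prconn: float = 0.5       # per-site occupation probability
    delta_conn: float = 10.0  # nm, connection site spacing
    sigma_conn: float = 10.0  # nm, connection point jitter sd
    rho_noise: float = 0.0    # μm⁻², uniform background intensity
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.L, self.sigma_em, self.b, self.delta_conn, self.sigma_conn) <= 0:
            raise ValueError("lengths must be positive")
        if self.n_clusters < 1 or self.n_emitters < 1:
            raise ValueError("n_clusters and n_emitters must be at least 1")
        for p in (self.pr_nominal, self.prconn):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.rho_noise < 0:
            raise ValueError("rho_noise must be non-negative")

    @property
    def rho_cl(self) -> float:
        """Cluster density Ncl/L² in μm⁻²."""
        return self.n_clusters / self.L**2

    @property
    def r_cl(self) -> float:
        """Effective cluster radius 2σem in nm (95% of a 2D Gaussian)."""
        return 2.0 * self.sigma_em

    @property
    def rho_em(self) -> float:
        """Internal emitter density Nem/(π·Rcl²) in μm⁻²."""
        r_um = self.r_cl / NM_PER_UM
        return self.n_emitters / (math.pi * r_um**2)


@dataclass(frozen=True)
class SimulationResult:
    """Generated table plus ground truth (nm coordinates throughout)."""

    table: LocalizationTable
    centers: np.ndarray                     # (Ncl, 2) nm
    connections: tuple[tuple[int, int], ...]
    realized_pr: float
    origin: np.ndarray                      # per-point tag array (see below)
    clipped: bool                           # per-pair probability hit 1.0
    config: SimulationConfig

    # origin tags: cluster points carry the cluster index (>= 0), connection
    # points carry -(pair_index) - 2, noise points carry -1


ORIGIN_NOISE = -1


def origin_is_cluster(origin: np.ndarray) -> np.ndarray:
    return origin >= 0


def origin_is_connection(origin: np.ndarray) -> np.ndarray:
    return origin <= -2


def simulate_dataset(config: SimulationConfig) -> SimulationResult:
    """Generate one connected-cluster dataset, reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    L_nm = config.L * NM_PER_UM
    ncl = config.n_clusters

    centers = rng.uniform(0.0, L_nm, size=(ncl, 2))

    # cluster emitters
    emitters = (
        centers[:, None, :]
        + rng.normal(0.0, config.sigma_em, size=(ncl, config.n_emitters, 2))
    ).reshape(-1, 2)
    origin = np.repeat(np.arange(ncl), config.n_emitters)

    # connections between eligible pairs
    connections: list[tuple[int, int]] = []
    conn_points: list[np.ndarray] = []
    conn_origin: list[np.ndarray] = []
    clipped = False
    if config.pr_nominal > 0:
        if ncl < 2:
            raise ValueError("connections require at least 2 clusters")
        n_total_pairs = ncl * (ncl - 1) // 2
        iu, ju = np.triu_indices(ncl, k=1)
        dist = np.linalg.norm(centers[iu] - centers[ju], axis=1)
        eligible = dist < config.b * NM_PER_UM
        n_eligible = int(eligible.sum())
        if n_eligible > 0:
            p_pair = config.pr_nominal * n_total_pairs / n_eligible
            if p_pair > 1.0:
                clipped = True
                p_pair = 1.0
            drawn = eligible & (rng.random(len(iu)) < p_pair)
            for pair_idx, (i, j) in enumerate(zip(iu[drawn], ju[drawn])):
                connections.append((int(i), int(j)))
                pts = _connection_points(
                    centers[i], centers[j], config, rng
                )
                if len(pts):
                    conn_points.append(pts)
                    conn_origin.append(
                        np.full(len(pts), -(pair_idx) - 2, dtype=np.int64)
                    )

    # uniform background noise: homogeneous Poisson process over the box
    n_noise = rng.poisson(config.rho_noise * config.L**2)
    noise = rng.uniform(0.0, L_nm, size=(n_noise, 2))

    parts = [emitters] + conn_points + [noise]
    origins = (
        [origin]
        + conn_origin
        + [np.full(n_noise, ORIGIN_NOISE, dtype=np.int64)]
    )
    xy = np.concatenate(parts)
    origin_all = np.concatenate(origins)

    n_total_pairs = ncl * (ncl - 1) // 2
    realized_pr = len(connections) / n_total_pairs if n_total_pairs else 0.0
    table = LocalizationTable.from_xy(xy, source_id=f"sim(seed={config.seed})")
    return SimulationResult(
        table=table,
        centers=centers,
        connections=tuple(connections),
        realized_pr=realized_pr,
        origin=origin_all,
        clipped=clipped,
        config=config,
    )


def _connection_points(
    c1: np.ndarray, c2: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Occupied, jittered sites along the open segment from c1 to c2 (nm)."""
    d = float(np.linalg.norm(c2 - c1))
    n_sites = math.ceil(d / config.delta_conn) - 1  # arclengths kΔ < d, k >= 1
    if n_sites <= 0:
        return np.empty((0, 2))
    t = config.delta_conn * np.arange(1, n_sites + 1) / d
    sites = c1 + t[:, None] * (c2 - c1)
    occupied = rng.random(n_sites) < config.prconn
    sites = sites[occupied]
    if len(sites) == 0:
        return np.empty((0, 2))
    return sites + rng.normal(0.0, config.sigma_conn, size=sites.shape)


def add_noise(
    table: LocalizationTable, rho_noise: float, L: float, seed: int
) -> LocalizationTable:
    """Append a homogeneous Poisson point process of intensity ρn (μm⁻²).

    The expected added count is ρn·L² with L in μm; points are uniform over
    the [0, L]² box. ρn = 0 returns the table unchanged.
    """
    if rho_noise < 0:
        raise ValueError("rho_noise must be non-negative")
    if rho_noise == 0:
        return table
    rng = np.random.default_rng(seed)
    n = rng.poisson(rho_noise * L**2)
    pts = rng.uniform(0.0, L * NM_PER_UM, size=(n, 2))
    extra = pd.DataFrame({"x": pts[:, 0], "y": pts[:, 1]})
    data = pd.concat([table.data, extra], ignore_index=True)
    return LocalizationTable(data, source_id=table.source_id)


def simulate_uniform_cluster(
    n_emitters: int, r_cl: float, seed: int
) -> LocalizationTable:
    """Points uniform in a disc of radius Rcl (nm): one idealized cluster.

    Area-uniform sampling (radius drawn as Rcl·√u) gives an average density
    ρem = Nem/(π·Rcl²); the count in any ε-disc inside the cluster is then
    Poisson-like with mean π·ρem·ε², the setting in which the intra-cluster
    avoidance model is exact.
    """
    if n_emitters < 1:
        raise ValueError("n_emitters must be at least 1")
    if r_cl <= 0:
        raise ValueError("r_cl must be positive")
    rng = np.random.default_rng(seed)
    r = r_cl * np.sqrt(rng.random(n_emitters))
    theta = rng.uniform(0.0, 2.0 * math.pi, n_emitters)
    xy = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    return LocalizationTable.from_xy(xy, source_id=f"uniform-disc(seed={seed})")


def replica_seeds(master_seed: int, n: int) -> list[int]:
    """Derive n independent per-replica seeds from one master seed.

    Uses numpy's SeedSequence spawning, so replicas are statistically
    independent and the whole set is reproducible from the master seed.
    """
    ss = np.random.SeedSequence(master_seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]
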