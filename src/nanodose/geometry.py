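"""Nanoparticle cluster geometry and the radial shell detector.

The cluster model: ``n`` identical core-shell nanoparticles (iron-oxide
core r = 3 nm, optional 1 nm radiolabel ring at r = 3-4 nm, polymer coat
out to r = 8.5 nm) packed without overlap inside a cubic water phantom.
Cluster compactness is controlled by the maximum separation distance
``sd_max``: every particle's nearest-neighbour surface-to-surface gap is
at most ``sd_max`` nm.  Placement is sequential: the first particle sits
at the box centre; each subsequent one attaches with a uniform surface
gap in [0, sd_max] to an anchor biased toward the cluster centroid,
rejecting overlaps and box exits and keeping the centroid-nearest of a
few valid candidates.  This produces a connected, compact cluster whose
inter-particle gaps never exceed sd_max.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

from .constants import (
    AVOGADRO,
    DEFAULT_BOX_NM,
    DEFAULT_N_NP,
    FE_ATOMS_PER_NP,
    NM3_TO_LITER,
    NP_CORE_RADIUS_NM,
    NP_LABEL_INNER_NM,
    NP_LABEL_OUTER_NM,
    NP_OUTER_RADIUS_NM,
)

__all__ = [
    "Nanoparticle",
    "NPCluster",
    "ShellDetector",
    "PackingInfeasibleError",
    "generate_cluster",
    "check_overlaps",
    "label_random",
    "fe_concentration",
    "sample_decay_origin",
    "build_shell_detector",
]

_CONTACT_TOL_NM = 1e-6  # sd_max = 0 means surface contact within this gap


class PackingInfeasibleError(RuntimeError):
    def __init__(self, placed: int, requested: int):
        self.placed = placed
        self.requested = requested
        super().__init__(
            f"could only place {placed} of {requested} nanoparticles")


@dataclass(frozen=True)
class Nanoparticle:
    center_nm: tuple[float, float, float]
    labeled: bool = False
    core_radius_nm: float = NP_CORE_RADIUS_NM
    coat_outer_radius_nm: float = NP_OUTER_RADIUS_NM

    @property
    def label_layer_nm(self) -> tuple[float, float] | None:
        return (NP_LABEL_INNER_NM, NP_LABEL_OUTER_NM) if self.labeled else None


@dataclass(frozen=True)
class NPCluster:
    """Positions (n, 3) and label flags of a packed nanoparticle cluster."""

    centers_nm: np.ndarray
    labeled: np.ndarray  # bool mask
    box_nm: float
    sd_max_nm: float
    seed: int
    outer_radius_nm: float = NP_OUTER_RADIUS_NM

    def __post_init__(self):
        object.__setattr__(self, "centers_nm",
                           np.ascontiguousarray(self.centers_nm, dtype=float))
        object.__setattr__(self, "labeled",
                           np.ascontiguousarray(self.labeled, dtype=bool))

    @property
    def n(self) -> int:
        return len(self.centers_nm)

    @property
    def labeled_indices(self) -> np.ndarray:
        return np.flatnonzero(self.labeled)

    def particles(self) -> list[Nanoparticle]:
        return [Nanoparticle(tuple(c), bool(l))
                for c, l in zip(self.centers_nm, self.labeled)]

    def nearest_neighbor_gaps(self) -> np.ndarray:
        """Surface-to-surface gap to each particle's nearest neighbour."""
        if self.n < 2:
            return np.empty(0)
        tree = cKDTree(self.centers_nm)
        dist, _ = tree.query(self.centers_nm, k=2)
        return dist[:, 1] - 2.0 * self.outer_radius_nm


def check_overlaps(cluster: NPCluster) -> list[tuple[int, int, float]]:
    """All-pairs overlap check; empty list iff no two spheres intersect.

    Returns (i, j, center distance) for every violating pair.  Brute force
    on purpose -- this is the oracle the fast packing path is checked
    against.
    """
    c = cluster.centers_nm
    n = len(c)
    if n < 2:
        return []
    d = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=-1)
    iu, ju = np.triu_indices(n, k=1)
    bad = d[iu, ju] <= 2.0 * cluster.outer_radius_nm
    return [(int(i), int(j), float(d[i, j]))
            for i, j in zip(iu[bad], ju[bad])]


def generate_cluster(n: int = DEFAULT_N_NP,
                     box_nm: float = DEFAULT_BOX_NM,
                     outer_radius_nm: float = NP_OUTER_RADIUS_NM,
                     sd_max_nm: float = 50.0,
                     seed: int = 0,
                     n_labeled: int = 0,
                     max_attempts_per_np: int = 5000) -> NPCluster:
    """Pack ``n`` non-overlapping spheres with gap constraint ``sd_max_nm``.

    Deterministic for a fixed seed.  Raises :class:`PackingInfeasibleError`
    when the attempt budget is exhausted.
    """
    if n < 1:
        raise ValueError("need at least one nanoparticle")
    r = outer_radius_nm
    half = box_nm / 2.0 - r
    if half < 0:
        raise ValueError("box too small for a single nanoparticle")
    vol_frac = n * (4.0 / 3.0) * np.pi * r**3 / box_nm**3
    if vol_frac >= 0.3:
        raise ValueError(f"packing fraction {vol_frac:.2f} too high")
    rng = np.random.default_rng(seed)
    gap_hi = max(sd_max_nm, _CONTACT_TOL_NM)

    centers = np.empty((n, 3))
    centers[0] = 0.0  # phantom-centred frame
    placed = 1
    centroid = np.zeros(3)
    tree = None
    tree_n = 0
    rebuild_every = 64
    n_anchor_draws = 4   # compactness: favour anchors near the centroid
    n_candidates = 3     # ... and keep the centroid-nearest valid position
    while placed < n:
        best = None
        best_d2c = np.inf
        found = 0
        for _ in range(max_attempts_per_np):
            # anchor: the centroid-nearest of a few uniformly drawn placed
            # particles; surface gap uniform in [0, sd_max]
            picks = rng.integers(placed, size=min(n_anchor_draws, placed))
            d2c = np.sum((centers[picks] - centroid) ** 2, axis=1)
            anchor = centers[picks[np.argmin(d2c)]]
            dist = 2 * r + rng.uniform(0.0, gap_hi)
            costh = rng.uniform(-1, 1)
            phi = rng.uniform(0, 2 * np.pi)
            sinth = np.sqrt(1 - costh**2)
            cand = anchor + dist * np.array(
                [sinth * np.cos(phi), sinth * np.sin(phi), costh])
            if np.any(np.abs(cand) > half):
                continue
            if tree is not None and tree.query_ball_point(cand, 2 * r + 1e-12):
                continue
            d2 = np.sum((centers[tree_n:placed] - cand) ** 2, axis=1)
            if np.any(d2 <= (2 * r) ** 2):
                continue
            d2c = float(np.sum((cand - centroid) ** 2))
            if d2c < best_d2c:
                best, best_d2c = cand, d2c
            found += 1
            if found >= n_candidates:
                break
        if best is None:
            raise PackingInfeasibleError(placed, n)
        centers[placed] = best
        centroid += (best - centroid) / (placed + 1)
        placed += 1
        if placed - tree_n >= rebuild_every:
            tree = cKDTree(centers[:placed])
            tree_n = placed
    cluster = NPCluster(centers_nm=centers,
                        labeled=np.zeros(n, dtype=bool),
                        box_nm=box_nm, sd_max_nm=sd_max_nm, seed=seed,
                        outer_radius_nm=outer_radius_nm)
    if n_labeled:
        cluster = label_random(cluster, n_labeled, seed=seed + 1)
    return cluster


def label_random(cluster: NPCluster, k: int, seed: int = 0) -> NPCluster:
    """Mark ``k`` particles, chosen uniformly without replacement, as labeled."""
    if k > cluster.n:
        raise ValueError(f"cannot label {k} of {cluster.n} nanoparticles")
    rng = np.random.default_rng(seed)
    idx = rng.choice(cluster.n, size=k, replace=False)
    labeled = np.zeros(cluster.n, dtype=bool)
    labeled[idx] = True
    return replace(cluster, labeled=labeled)


def fe_concentration(cluster: NPCluster) -> float:
    """Iron concentration of the dispersion in mmol per litre.

    n_NP x 5874 Fe atoms per particle over the box volume.
    """
    box_liters = cluster.box_nm**3 * NM3_TO_LITER
    if box_liters <= 0:
        raise ValueError("box volume must be positive")
    mol = cluster.n * FE_ATOMS_PER_NP / AVOGADRO
    return mol / box_liters * 1e3


def sample_decay_origin(cluster: NPCluster, labeled_index: int,
                        rng: np.random.Generator, size: int = 1) -> np.ndarray:
    """Uniform points in the radiolabel ring (r in [3, 4] nm) of one particle."""
    if not cluster.labeled[labeled_index]:
        raise ValueError(f"nanoparticle {labeled_index} is not labeled")
    return sample_annulus(np.asarray(cluster.centers_nm[labeled_index]),
                          NP_LABEL_INNER_NM, NP_LABEL_OUTER_NM, rng, size)


def sample_annulus(center: np.ndarray, r_in: float, r_out: float,
                   rng: np.random.Generator, size: int) -> np.ndarray:
    """Uniform points in a spherical annulus (volume-weighted radii)."""
    u = rng.random(size)
    r = (r_in**3 + u * (r_out**3 - r_in**3)) ** (1.0 / 3.0)
    costh = rng.uniform(-1, 1, size)
    phi = rng.uniform(0, 2 * np.pi, size)
    sinth = np.sqrt(1 - costh**2)
    pts = np.column_stack((r * sinth * np.cos(phi),
                           r * sinth * np.sin(phi),
                           r * costh))
    return pts + center


@dataclass(frozen=True)
class ShellDetector:
    """Concentric 1 nm spherical shells around one nanoparticle.

    Mirrors the radial-dose detector: shells run from the particle surface
    (8.5 nm) out to 100 nm by default.
    """

    center_nm: np.ndarray
    boundaries_nm: np.ndarray  # strictly increasing, len n_shells + 1

    @property
    def n_shells(self) -> int:
        return len(self.boundaries_nm) - 1

    @property
    def inner_nm(self) -> float:
        return float(self.boundaries_nm[0])

    @property
    def outer_nm(self) -> float:
        return float(self.boundaries_nm[-1])

    def shell_volumes_nm3(self) -> np.ndarray:
        b = self.boundaries_nm
        return 4.0 / 3.0 * np.pi * (b[1:] ** 3 - b[:-1] ** 3)

    def shell_index(self, positions_nm: np.ndarray) -> np.ndarray:
        """Shell index per position; -1 below inner, n_shells beyond outer."""
        r = np.linalg.norm(np.atleast_2d(positions_nm) - self.center_nm, axis=1)
        idx = np.searchsorted(self.boundaries_nm, r, side="right") - 1
        idx[r < self.inner_nm] = -1
        idx[r >= self.outer_nm] = self.n_shells
        return idx


def build_shell_detector(center_nm=(0.0, 0.0, 0.0),
                         inner_nm: float = NP_OUTER_RADIUS_NM,
                         width_nm: float = 1.0,
                         outer_nm: float = 100.0) -> ShellDetector:
    """Equidistant shells from ``inner`` to ``outer``; last shell truncated."""
    if not inner_nm < outer_nm:
        raise ValueError("inner radius must be below outer radius")
    edges = np.arange(inner_nm, outer_nm, width_nm)
    boundaries = np.append(edges, outer_nm)
    if boundaries[-1] - boundaries[-2] < 1e-12:
        boundaries = boundaries[:-1]
    return ShellDetector(center_nm=np.asarray(center_nm, dtype=float),
                         boundaries_nm=boundaries)
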