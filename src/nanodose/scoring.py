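"""Scoring actors: voxel dose, per-nanoparticle hit tallies, secondary
spectra / Auger counts, and radial shell dose.

All scorers expose the columnar batch hooks the transport engine calls
(``score_deposit_batch``, ``score_interaction_batch``,
``score_secondary_batch``) plus scalar convenience methods.  Dose is
scored in water only by default -- deposits tagged inside a nanoparticle
go to a separate ledger, not the dose grid, mirroring the convention
that nanoparticle self-absorption is not part of the water dose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import KEV_TO_JOULE, NM_TO_CM, WATER_DENSITY_G_CM3
from .geometry import NPCluster, ShellDetector
from .materials import REGION_CORE, REGION_LABEL, REGION_WATER

__all__ = [
    "DoseGrid", "HitTally", "SpectrumHistogram", "RadialDoseProfile",
    "dose_gray", "project_2d", "tally_hits", "record_secondary",
]


def dose_gray(energy_kev: float | np.ndarray, mass_kg: float | np.ndarray):
    """Absorbed dose in Gy: E [keV] x 1.602176634e-16 J/keV / mass [kg]."""
    mass = np.asarray(mass_kg, dtype=float)
    if np.any(mass <= 0):
        raise ValueError("mass must be positive")
    return np.asarray(energy_kev, dtype=float) * KEV_TO_JOULE / mass


def _voxel_mass_kg(voxel_nm: float) -> float:
    vol_cm3 = (voxel_nm * NM_TO_CM) ** 3
    return WATER_DENSITY_G_CM3 * vol_cm3 * 1e-3


class DoseGrid:
    """Uniform voxel grid over the phantom scoring water deposits (keV).

    Voxel mass assumes unit-density water everywhere (the nanoparticle
    volume fraction is ~1e-6).  Deposits tagged in-NP are accumulated in
    ``np_energy_kev``; deposits outside the grid go to ``overflow_kev``
    (never silently dropped).
    """

    def __init__(self, box_nm: float, n_voxels: int = 70,
                 score_in_np: bool = False):
        self.box_nm = float(box_nm)
        self.n = int(n_voxels)
        self.voxel_nm = self.box_nm / self.n
        self.energy_kev = np.zeros((self.n, self.n, self.n))
        self.np_energy_kev = 0.0
        self.overflow_kev = 0.0
        self.score_in_np = score_in_np

    def _indices(self, pos_nm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ijk = np.floor((pos_nm + self.box_nm / 2.0) / self.voxel_nm).astype(int)
        ok = np.all((ijk >= 0) & (ijk < self.n), axis=1)
        return ijk, ok

    def score_deposit_batch(self, pos, edep, region, np_idx, hist, ptype):
        edep = np.asarray(edep, dtype=float)
        # coating region counts as water phantom; only core/label excluded
        in_water = (region != REGION_CORE) & (region != REGION_LABEL)
        if not self.score_in_np:
            self.np_energy_kev += float(edep[~in_water].sum())
            pos, edep = pos[in_water], edep[in_water]
        ijk, ok = self._indices(pos)
        self.overflow_kev += float(edep[~ok].sum())
        ijk, edep = ijk[ok], edep[ok]
        np.add.at(self.energy_kev,
                  (ijk[:, 0], ijk[:, 1], ijk[:, 2]), edep)

    def score_deposit(self, pos_nm, energy_kev: float, region: int = REGION_WATER):
        """Scalar convenience wrapper."""
        self.score_deposit_batch(np.atleast_2d(np.asarray(pos_nm, float)),
                                 np.array([energy_kev]),
                                 np.array([region], dtype=np.int8),
                                 np.array([-1]), np.array([0]), 0)

    @property
    def voxel_mass_kg(self) -> float:
        return _voxel_mass_kg(self.voxel_nm)

    def dose_gy(self) -> np.ndarray:
        return dose_gray(self.energy_kev, self.voxel_mass_kg)

    def total_energy_kev(self) -> float:
        return float(self.energy_kev.sum())

    def total_dose_gy(self) -> float:
        """Total integrated dose: summed voxel doses."""
        return float(self.dose_gy().sum())


def project_2d(grid: DoseGrid, axis: str | int = "z") -> np.ndarray:
    """2D dose histogram (Gy) integrating the 3D energy along one axis.

    Column mass = voxel mass x n voxels, so the total projected dose
    equals the total 3D dose.
    """
    ax = {"x": 0, "y": 1, "z": 2}.get(axis, axis)
    if ax not in (0, 1, 2):
        raise ValueError(f"invalid axis {axis!r}")
    energy_2d = grid.energy_kev.sum(axis=ax)
    return dose_gray(energy_2d, grid.voxel_mass_kg)


class HitTally:
    """Per-nanoparticle count of discrete interaction events.

    A hit is any discrete interaction (delta-ray production, photon
    interaction) whose location lies inside an NP's outer radius.
    """

    def __init__(self, cluster: NPCluster):
        self.cluster = cluster
        self.counts = np.zeros(cluster.n, dtype=np.int64)

    def score_interaction_batch(self, pos, np_idx, hist):
        inside = np_idx >= 0
        if inside.any():
            np.add.at(self.counts, np_idx[inside], 1)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def tally_hits(positions_nm: np.ndarray, cluster: NPCluster) -> HitTally:
    """Tally point events against a cluster by point-in-sphere test."""
    tally = HitTally(cluster)
    pos = np.atleast_2d(np.asarray(positions_nm, dtype=float))
    d = np.linalg.norm(pos[:, None, :] - cluster.centers_nm[None, :, :], axis=2)
    hit = d < cluster.outer_radius_nm
    # a point can only be inside one sphere (non-overlapping cluster)
    np_idx = np.where(hit.any(axis=1), hit.argmax(axis=1), -1)
    tally.score_interaction_batch(pos, np_idx, np.zeros(len(pos), dtype=int))
    return tally


class SpectrumHistogram:
    """Energy histogram of secondary electrons born between nanoparticles.

    Binned only when the creation position lies outside every NP outer
    radius (region == water); Auger-subtype electrons additionally
    increment ``auger_count`` regardless of birth region, so the Auger
    production bookkeeping includes electrons released inside the
    nanoparticles.
    """

    def __init__(self, e_min_kev: float = 0.01, e_max_kev: float = 10.0,
                 bin_width_kev: float = 0.01,
                 roi_center_nm=None, roi_radius_nm: float | None = None):
        self.edges_kev = np.arange(e_min_kev, e_max_kev + bin_width_kev / 2,
                                   bin_width_kev)
        self.counts = np.zeros(len(self.edges_kev) - 1, dtype=np.int64)
        self.accepted = 0
        self.auger_count = 0
        self.auger_count_water = 0
        # optional spherical region of interest: "the space between the
        # nanoparticles" is the water inside the cluster envelope, not the
        # whole phantom
        self.roi_center_nm = None if roi_center_nm is None             else np.asarray(roi_center_nm, dtype=float)
        self.roi_radius_nm = roi_radius_nm

    def score_secondary_batch(self, energy, pos, region, hist, is_auger):
        energy = np.asarray(energy, dtype=float)
        is_auger = np.asarray(is_auger, dtype=bool)
        self.auger_count += int(is_auger.sum())
        in_water = np.asarray(region) == REGION_WATER
        self.auger_count_water += int((is_auger & in_water).sum())
        accept = in_water
        if self.roi_center_nm is not None:
            r = np.linalg.norm(np.atleast_2d(pos) - self.roi_center_nm,
                               axis=1)
            accept = accept & (r <= self.roi_radius_nm)
        e_w = energy[accept]
        self.accepted += len(e_w)
        self.counts += np.histogram(e_w, bins=self.edges_kev)[0]

    def normalized(self) -> np.ndarray:
        total = self.counts.sum()
        return self.counts / total if total else self.counts.astype(float)


def record_secondary(energy_kev: float, position_nm, region: int,
                     spectrum: SpectrumHistogram,
                     is_auger: bool = False) -> SpectrumHistogram:
    """Record one secondary electron (scalar wrapper)."""
    spectrum.score_secondary_batch(np.array([energy_kev]),
                                   np.atleast_2d(np.asarray(position_nm)),
                                   np.array([region], dtype=np.int8),
                                   np.array([0]), np.array([is_auger]))
    return spectrum


class RadialDoseProfile:
    """Dose per 1 nm concentric shell around a nanoparticle (water only)."""

    def __init__(self, detector: ShellDetector):
        self.detector = detector
        self.energy_kev = np.zeros(detector.n_shells)
        self.overflow_kev = 0.0
        self.inner_kev = 0.0

    def score_deposit_batch(self, pos, edep, region, np_idx, hist, ptype):
        edep = np.asarray(edep, dtype=float)
        in_water = (region != REGION_CORE) & (region != REGION_LABEL)
        pos, edep = pos[in_water], edep[in_water]
        if not len(edep):
            return
        idx = self.detector.shell_index(pos)
        below = idx < 0
        above = idx >= self.detector.n_shells
        ok = ~below & ~above
        self.inner_kev += float(edep[below].sum())
        self.overflow_kev += float(edep[above].sum())
        np.add.at(self.energy_kev, idx[ok], edep[ok])

    def shell_masses_kg(self) -> np.ndarray:
        vol_cm3 = self.detector.shell_volumes_nm3() * NM_TO_CM**3
        return WATER_DENSITY_G_CM3 * vol_cm3 * 1e-3

    def dose_gy(self, scale: float = 1.0) -> np.ndarray:
        return dose_gray(self.energy_kev * scale, self.shell_masses_kg())

    def radii_nm(self) -> np.ndarray:
        b = self.detector.boundaries_nm
        return 0.5 * (b[1:] + b[:-1])
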