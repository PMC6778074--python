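"""Loaders and interpolators for the packaged stopping-power and
attenuation tables.

Charged-particle stopping powers are interpolated log-log; below the
lowest tabulated energy the stopping power is clamped to the first node
(the empirical low-energy plateau), above the highest an extrapolation
error is raised.  CSDA ranges integrate the reciprocal stopping power by
adaptive quadrature.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
from scipy.integrate import quad

from .materials import Material, WATER

__all__ = [
    "StoppingTable", "AttenuationTable", "FeAtomicData",
    "electron_stopping_table", "alpha_stopping_table", "attenuation_table",
    "fe_atomic_data", "stopping_power", "electron_range",
]


class ExtrapolationError(ValueError):
    """Energy outside the tabulated range."""


def _read_columns(fname: str, ncols: int) -> np.ndarray:
    path = resources.files("nanodose.data.physics").joinpath(fname)
    rows = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        rows.append([float(x) for x in parts[:ncols]])
    return np.asarray(rows)


@dataclass(frozen=True)
class StoppingTable:
    """Log-log interpolated stopping power S(E), keV/nm, E in keV."""

    material: str
    energy_kev: np.ndarray
    s_kev_nm: np.ndarray
    density_scale: float = 1.0  # linear density scaling knob

    def __call__(self, e_kev) -> np.ndarray:
        e = np.asarray(e_kev, dtype=float)
        scalar = e.ndim == 0
        e = np.atleast_1d(e)
        if np.any(e > self.energy_kev[-1] * (1 + 1e-9)):
            raise ExtrapolationError(
                f"{self.material}: energy above table maximum "
                f"{self.energy_kev[-1]} keV")
        out = np.empty_like(e)
        lo = e <= self.energy_kev[0]
        out[lo] = self.s_kev_nm[0]
        hi = ~lo
        out[hi] = np.exp(np.interp(np.log(e[hi]), np.log(self.energy_kev),
                                   np.log(self.s_kev_nm)))
        out *= self.density_scale
        return float(out[0]) if scalar else out

    def scaled(self, factor: float) -> "StoppingTable":
        return StoppingTable(self.material, self.energy_kev, self.s_kev_nm,
                             self.density_scale * factor)

    def csda_range_nm(self, e_kev: float) -> float:
        """Continuous-slowing-down range, integral of dE'/S(E') from 0."""
        if e_kev <= 0:
            return 0.0
        nodes = self.energy_kev[self.energy_kev < e_kev]
        r, _ = quad(lambda x: 1.0 / self(x), 0.0, e_kev, limit=400,
                    points=nodes[-48:] if len(nodes) else None)
        return r


@lru_cache(maxsize=None)
def electron_stopping_table(material: str = "water") -> StoppingTable:
    data = _read_columns(f"electron_stopping_{material}.tsv", 2)
    return StoppingTable(material, data[:, 0] * 1e-3, data[:, 1] * 1e-3)


@lru_cache(maxsize=None)
def alpha_stopping_table(material: str = "water") -> StoppingTable:
    data = _read_columns("alpha_stopping_water.tsv", 2)
    table = StoppingTable("water", data[:, 0], data[:, 1] * 1e-3)
    if material == "water":
        return table
    # other materials: relative-electron-density scaling of the water table
    from .materials import MATERIALS
    mat = MATERIALS[material]
    return StoppingTable(material, table.energy_kev, table.s_kev_nm,
                         mat.electron_density_rel_water)


def stopping_power(e_kev, material: Material | str, ptype: str):
    """Collisional stopping power in keV/nm for ``ptype`` in a material."""
    name = material if isinstance(material, str) else material.name
    if ptype == "electron":
        return electron_stopping_table(name)(e_kev)
    if ptype == "alpha":
        return alpha_stopping_table(name)(e_kev)
    raise ValueError(f"no stopping table for particle type {ptype!r}")


def electron_range(e_kev: float, material: Material | str = "water") -> float:
    """CSDA range in nm by adaptive quadrature of 1/S."""
    name = material if isinstance(material, str) else material.name
    return electron_stopping_table(name).csda_range_nm(e_kev)


@dataclass(frozen=True)
class AttenuationTable:
    """Photon linear attenuation coefficients, 1/nm, log-log interpolated."""

    material: str
    energy_kev: np.ndarray
    mu_total_nm: np.ndarray
    mu_pe_nm: np.ndarray
    mu_incoh_nm: np.ndarray

    def _interp(self, e, col) -> np.ndarray:
        e = np.atleast_1d(np.asarray(e, dtype=float))
        if np.any(e < self.energy_kev[0] * (1 - 1e-9)) or \
           np.any(e > self.energy_kev[-1] * (1 + 1e-9)):
            raise ExtrapolationError(
                f"{self.material}: photon energy outside table")
        return np.exp(np.interp(np.log(e), np.log(self.energy_kev),
                                np.log(np.maximum(col, 1e-300))))

    def mu_total(self, e_kev) -> np.ndarray:
        return self._interp(e_kev, self.mu_total_nm)

    def mu_photoelectric(self, e_kev) -> np.ndarray:
        return self._interp(e_kev, self.mu_pe_nm)

    def mu_incoherent(self, e_kev) -> np.ndarray:
        return self._interp(e_kev, self.mu_incoh_nm)

    def attenuation_length_nm(self, e_kev) -> np.ndarray:
        return 1.0 / self.mu_total(e_kev)


@lru_cache(maxsize=None)
def attenuation_table(material: str = "water") -> AttenuationTable:
    data = _read_columns(f"photon_attenuation_{material}.tsv", 4)
    from .materials import MATERIALS
    rho = MATERIALS[material].density_g_cm3
    cm_to_nm = 1e-7  # mu [1/cm] -> [1/nm]
    return AttenuationTable(
        material, data[:, 0],
        data[:, 1] * rho * cm_to_nm,
        data[:, 2] * rho * cm_to_nm,
        data[:, 3] * rho * cm_to_nm,
    )


@dataclass(frozen=True)
class FeAtomicData:
    k_binding_kev: float
    l_binding_kev: float
    omega_k: float
    kalpha_kev: float
    kalpha_frac: float
    kbeta_kev: float
    kbeta_frac: float
    k_auger_kev: float
    l_auger_kev: float


@lru_cache(maxsize=None)
def fe_atomic_data() -> FeAtomicData:
    path = resources.files("nanodose.data.physics").joinpath("fe_atomic.tsv")
    kv = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        k, v = line.split()
        kv[k] = float(v)
    return FeAtomicData(**kv)
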