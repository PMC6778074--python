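"""Material definitions for the transport engine.

Four region materials: water, the iron-oxide (SPIO) core, the radiolabel
ring (modelled with core-like properties: a dense metal-bearing shell),
and the polymer coating.  Compositions follow the core/coat stoichiometry
Fe5874 O8752 : C11719 H18682 O9933 Na414; densities are model choices
(magnetite-like 5.2 g/cm3 core, 1.2 g/cm3 coat, unit-density water).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["Material", "WATER", "SPIO_CORE", "RADIO_LAYER", "COATING",
           "MATERIALS", "REGION_MATERIALS"]

_ZA = {"H": (1, 1.008), "C": (6, 12.011), "O": (8, 15.999),
       "Na": (11, 22.990), "Fe": (26, 55.845)}


@dataclass(frozen=True)
class Material:
    name: str
    density_g_cm3: float
    composition: tuple[tuple[str, float], ...]  # (element, mass fraction)
    mean_excitation_ev: float
    k_binding_kev: float   # dominant photo-absorber K-shell binding
    fe_bearing: bool = False

    def __post_init__(self):
        total = sum(w for _, w in self.composition)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: mass fractions sum to {total}")
        if self.mean_excitation_ev <= 0:
            raise ValueError(f"{self.name}: I must be positive")

    @property
    def z_over_a(self) -> float:
        return sum(w * _ZA[el][0] / _ZA[el][1] for el, w in self.composition)

    @property
    def electron_density_rel_water(self) -> float:
        """Electrons per volume relative to liquid water."""
        return self.density_g_cm3 * self.z_over_a / (1.0 * 0.55509)

    @property
    def effective_z(self) -> float:
        """Photoelectric-weighted effective atomic number (2.94 exponent)."""
        za = self.z_over_a
        acc = 0.0
        for el, w in self.composition:
            z, a = _ZA[el]
            acc += (w * z / a / za) * z**2.94
        return acc ** (1.0 / 2.94)


WATER = Material("water", 1.0, (("H", 0.1119), ("O", 0.8881)), 75.0,
                 k_binding_kev=0.543)
SPIO_CORE = Material("iron_oxide", 5.2, (("Fe", 0.7009), ("O", 0.2991)),
                     286.0, k_binding_kev=7.112, fe_bearing=True)
# radiolabel ring: a monolayer of radiometal atoms bound to the core
# surface; transported with core-like (dense metal-oxide) properties
RADIO_LAYER = Material("radio_layer", 5.2, (("Fe", 0.7009), ("O", 0.2991)),
                       286.0, k_binding_kev=7.112, fe_bearing=True)
COATING = Material("coating", 1.2,
                   (("C", 0.4291), ("H", 0.0574), ("O", 0.4845), ("Na", 0.0290)),
                   74.7, k_binding_kev=0.543)

MATERIALS = {m.name: m for m in (WATER, SPIO_CORE, RADIO_LAYER, COATING)}

# region codes used by the transport engine
REGION_WATER, REGION_CORE, REGION_LABEL, REGION_COAT = 0, 1, 2, 3
REGION_MATERIALS = {
    REGION_WATER: WATER,
    REGION_CORE: SPIO_CORE,
    REGION_LABEL: RADIO_LAYER,
    REGION_COAT: COATING,
}
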