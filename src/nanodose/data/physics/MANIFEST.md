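# Packaged physics tables

All tables are whitespace-delimited text with `#` comment headers and are
regenerated by `scripts/generate_physics_tables.py`.

| file | contents | provenance |
|---|---|---|
| `electron_stopping_<mat>.tsv` | electron collisional stopping power, eV/nm vs eV | >=1 keV: Berger–Seltzer (Bethe) formula with the material's mean excitation energy (water 75 eV, iron oxide 286 eV, coating 74.7 eV) and density; <1 keV: empirical liquid-water extension scaled by relative electron density. The sub-keV extension is anchored so that the CSDA range in water at 400–500 eV lies in the 12–18 nm window reported for low-energy electrons in liquid water. |
| `alpha_stopping_water.tsv` | alpha electronic stopping power, keV/µm vs keV | ASTAR-like hand-compiled nodes (rounded); other materials are obtained in code by relative-electron-density scaling. |
| `photon_attenuation_<mat>.tsv` | mass attenuation µ/ρ (total, photoelectric, incoherent), cm²/g vs keV | incoherent: Klein–Nishina per electron; photoelectric: Z^4.5/E^3 parametrization calibrated to water at 10 keV, Fe K-edge jump ratio 8.2. Coherent scattering omitted. |
| `fe_atomic.tsv` | Fe K/L binding energies, K fluorescence yield ω_K = 0.34, Kα/Kβ lines, KLL/L Auger energies | standard atomic-relaxation compilations, rounded. |

Nuclide decay data lives in `../nuclides/` (one file per nuclide, schema in
each header) and is compiled from standard nuclear-data evaluations
(NuDat/ENSDF-derived), rounded; intensities are per decay.
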