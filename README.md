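# nanodose

Decay-chain dosimetry and simplified Monte Carlo transport for studying
dose enhancement by radiolabeled superparamagnetic iron-oxide (SPIO)
nanoparticles in internal radionuclide therapy.

Clinically used radioisotopes (²¹³Bi, ²²³Ra, ⁹⁰Y, ¹⁷⁷Lu, ⁶⁷Cu, ⁶⁴Cu,
⁸⁹Zr) can be bound chelate-free in a 1 nm ring around the iron-oxide
core of a Feraheme-like nanoparticle.  When such particles cluster, the
electrons liberated by the decay radiation interact with neighbouring
high-Z cores and amplify the local energy deposition.  `nanodose` is a
self-contained pipeline for exploring that mechanism:

* **decay** — packaged nuclide data, chain-decay (Bateman) activities
  A_n(t), all-time disintegration budgets Ã = A₀/λ, and stochastic
  sampling of per-decay emission events (α, β± with Fermi-corrected
  allowed spectra, γ, Auger/conversion electrons);
* **geometry** — non-overlapping core–shell cluster generation with a
  maximum separation-distance (SD) constraint, radiolabel placement, and
  the 1 nm radial shell detector;
* **transport** — a vectorized condensed-history engine (continuous
  loss + 1/ε² delta rays, Fe K/L relaxation, Woodcock photon tracking,
  10 eV cuts, 1 nm steps near particles) with exact per-history energy
  bookkeeping;
* **scoring** — water-only voxel dose with 2D projections, per-particle
  hit tallies, between-particle secondary spectra and Auger counts,
  radial shell dose;
* **analysis** — dose enhancement DE(%) = (DER − 1) × 100 versus SD with
  paired with/without-nanoparticle arms, radial dose profiles, spectrum
  convergence, and labeling-capacity arithmetic.

The engine is an intentionally simplified stand-in for full-physics
codes: it reproduces signs, orderings and distance dependences, not
published percentages.  See `docs/methods.md` for the model, its
defaults and its limitations.

## Worked example

```python
>>> from nanodose import (build_chain, chain_cumulative_disintegrations,
...                       loading_capacity, electron_range)
>>> cum = chain_cumulative_disintegrations(build_chain("Ra-223", a0_bq=1000))
>>> round(cum.per_nuclide["Ra-223"] / 1e9, 2)
1.42
>>> lc = loading_capacity(92.5e6, "Zr-89", fe_mass_mg=1.0)
>>> f"{lc.radiometal_atoms:.2e} atoms on {lc.np_count:.2e} NPs -> 1:{lc.nps_per_atom:.0f}"
'3.77e+13 atoms on 1.84e+15 NPs -> 1:49'
>>> round(electron_range(0.4, "water"), 1), round(electron_range(0.5, "water"), 1)
(14.7, 17.7)
```

1 kBq of ²²³Ra delivers ≈1.4 × 10⁹ parent disintegrations over all time;
92.5 MBq of ⁸⁹Zr is ≈3.8 × 10¹³ atoms, about one radiometal atom per 49
nanoparticles in 1 mg Fe; and 400–500 eV secondary electrons — the peak
of the secondary spectrum — travel 14.7–17.7 nm in water, which sets the
inter-particle distance scale over which enhancement operates.

A dose-enhancement scan from the shell:

```sh
nanodose run-de --sd 1,10,25,50 --histories 600 --seed 11
```

prints DE(%) with batch uncertainties per separation distance (positive
at a few percent for compact clusters with an alpha source, falling
toward zero as the cluster disperses), and `nanodose radial --isotope
Bi-213` prints the radial shell dose around a single labeled particle.

The numbered scripts under `analysis/` run the individual studies
(decay budgets, cluster geometry, electron ranges, DE vs SD, radial
dose, spectra/Auger) and write their tables under `results/`.

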