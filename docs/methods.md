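# Methods

`nanodose` models the dose-enhancement physics of radiolabeled
superparamagnetic iron-oxide (SPIO) nanoparticles for internal
radionuclide therapy: clinically used isotopes (²¹³Bi, ²²³Ra, ⁹⁰Y,
¹⁷⁷Lu, ⁶⁷Cu, ⁶⁴Cu, ⁸⁹Zr) bound in a 1 nm ring around the 6 nm iron-oxide
core of a Feraheme-like core–shell nanoparticle (outer radius 8.5 nm),
with 500 such particles clustered in a 3.5 µm water box at ≈0.1 mM Fe,
10 of them radiolabeled, and 1 kBq of administered activity.

## Decay model

Each nuclide is a packaged record of half-life, decay modes with
branching fractions, and per-decay emission lines (α, γ, discrete
Auger/conversion electrons) plus β branches (endpoint, intensity, sign),
compiled from standard nuclear-data evaluations and rounded.  Chains are
resolved by walking the decay graph; members whose cumulative branching
falls below 10⁻⁶ are dropped.

Activities follow the classical chain-decay (Bateman) solution

A_n(t) = N₁(0) · (∏_{j<n} b_j λ_j) · λ_n · Σ_i e^{−λ_i t} / ∏_{j≠i} (λ_j − λ_i),

superposed over linear paths for branched graphs; equal decay constants
raise an error rather than taking a confluent limit (no packaged chain
needs one).  The all-time disintegration budget is Ã = A₀/λ for the
parent and branching-weighted shares for daughters.  β energies are
drawn from the allowed-transition shape p·W·(Q−E)² with the
non-relativistic Fermi Coulomb factor 2πη/(1−e^{−2πη}), η = ±Zα/β — an
approximation to the evaluated spectra, adequate here because transport,
not spectroscopy, consumes them.  Daughters decay at the parent atom's
position (no recoil transport).

The chain-aggregated "4 % β / 2 % γ" weighting conventions sometimes
quoted for ²²³Ra are not reproduced deliberately; per-decay intensities
are the packaged ground truth.

## Cluster geometry

Cluster compactness is controlled by the maximum separation distance
(SD): every particle's nearest-neighbour surface gap is ≤ SD
(SD = 0 means contact within 10⁻⁶ nm).  Particles are placed
sequentially: the anchor is the centroid-nearest of four uniformly drawn
already-placed particles, the surface gap is uniform in [0, SD] around
it, candidates overlapping any particle or leaving the box are rejected,
and the centroid-nearest of up to three valid candidates is kept.  The
centroid bias keeps growth compact (volume fraction ≈0.3 at SD ≤ 1 nm,
≈0.15 at SD = 50 nm, ≈0.002 at SD = 500 nm) while the gap draw still
scales with SD; a purely uniform anchor choice produces dendritic
aggregates (volume fraction ≈0.05) that do not resemble the dense
clusters this geometry is meant to emulate.  SD values above 50 nm
switch to a 100 µm phantom.

Layered radii are core 0–3 nm, radiolabel ring 3–4 nm, coat 4–8.5 nm.
The nominal 6 nm core + 1 nm ring + 5.5 nm coat would give a 9.5 nm
outer radius; the stated ≈17 nm overall diameter wins and the coat is
thinned accordingly.  Densities: core and ring 5.2 g/cm³
(magnetite-like), coat 1.2 g/cm³, water 1.0 g/cm³ — the stoichiometry
(Fe₅₈₇₄O₈₇₅₂ : C₁₁₇₁₉H₁₈₆₈₂O₉₉₃₃Na₄₁₄) is given, densities are model
choices.

## Transport engine

A deliberately simplified condensed-history Monte Carlo stands in for a
full GEANT4-class code.  Its components:

* **Stopping powers.** Electrons: Berger–Seltzer (Bethe) collisional
  stopping above 1 keV with material mean excitation energies (water
  75 eV, iron oxide 286 eV, coat 74.7 eV); below 1 keV an empirical
  liquid-water extension scaled by relative electron density, anchored
  so the CSDA range in water is 14.7 nm at 400 eV and 17.7 nm at 500 eV
  (inside the 12–18 nm window reported for liquid water).  Alphas:
  ASTAR-like water nodes, other materials by electron-density scaling.
  The sub-keV extension is the dominant systematic of the engine.
* **Stepping.** Step = min(0.1 × residual range while range ≥ 100 nm,
  1 nm near/inside nanoparticles, exact ray–sphere distance to the
  nearest particle surfaces).  In bulk water a step may stretch to the
  distance back to the 20 nm near-zone (cap 1 µm) with delta-ray
  production Poisson-distributed along it; segments that provably stay
  clear of every particle skip region classification.  Continuous loss
  (the `1 − delta_fraction` share) is deposited at the step midpoint.
* **Delta rays.** A fixed fraction (default 0.9) of the collisional
  stopping power is carried by explicit secondaries with a
  binary-encounter-like 1/ε² transfer spectrum between the 10 eV
  production cut and ε_max (E/2 for electrons, 2m_ev² for alphas).  With
  a 10 eV cut nearly all collisional loss is discrete, hence the high
  default.  Secondaries below 100 eV (range ≲ 4 nm) are not stepped:
  their energy is deposited at the birth point displaced by a random
  fraction of their residual range.  Multiple scattering is a Gaussian
  small-angle model per step.
* **Atomic relaxation.** A delta transfer in Fe-bearing material that
  exceeds a shell binding creates that vacancy (K 7.112 keV,
  L 0.72 keV); K vacancies fluoresce with ω_K = 0.34 (Kα/Kβ) else eject
  a KLL Auger electron, L vacancies eject an L-Auger electron; the
  binding remainder is deposited locally, so energy balances exactly.
* **Photons.** Woodcock (delta-)tracking on packaged attenuation tables
  (Klein–Nishina incoherent + a Z^4.5/E³ photoelectric parametrization
  calibrated to water at 10 keV, Fe K-edge jump 8.2; coherent scattering
  and pair production ignored).  Compton electrons get E − E′; scattered
  photons are re-emitted isotropically (a simplification; photon dose in
  these phantoms is negligible).  Positrons transport as electrons and
  annihilate at rest into two 511 keV photons (added to the emitted
  ledger).
* **Cuts.** Tracking and production cuts are 10 eV; sub-cut particles
  deposit locally.

Per-history bookkeeping satisfies emitted = water-deposit + NP-deposit +
escaped to ≲10⁻¹² relative.  Identical seeds give bitwise-identical
results; replacing every nanoparticle material by water in both arms of
a paired comparison gives a dose-enhancement of exactly zero.

## Scoring

Dose is recorded for the water phantom only: deposits inside the core
and radiolabel ring count as nanoparticle self-absorption and are
excluded; the coat region is scored as part of the water phantom (it is
water-like in density and composition, and the convention mirrors
scoring dose "for the water phantom only" while self-absorption means
absorption in the metal core).  Voxel dose uses a 70³ grid (50 nm
voxels — the grid size is a choice; the reference study does not state
one) at unit water density; 2D projections conserve the integrated
dose exactly.  A "hit" is any discrete interaction (delta production or
photon interaction) inside a particle's outer radius.  The secondary
spectrum records electrons born in the water between the nanoparticles —
implemented as water-region births inside the sphere enclosing the
cluster — in 10 eV bins from 10 eV to 10 keV; the Auger counter counts
Auger-subtype electrons born anywhere (including inside particles),
with a water-only count kept alongside.  The radial detector is 92
concentric 1 nm shells from the particle surface (8.5 nm) to 100 nm.

## Dose-enhancement experiments

DE(%) = (DER − 1) × 100 with DER the ratio of total water-deposited
energy with nanoparticles present to that with the nanoparticle material
replaced by water.  The two arms share the emission stream and transport
seed (paired comparison; the reference study ran independent arms — this
changes the variance, not the expectation).  Uncertainties come from
history batches.  Radial-dose studies place one labeled particle at the
centre of a 1 µm box and scale the per-history tally to the full Ã of
1 kBq; the therapeutic five (²¹³Bi, ²²³Ra, ⁹⁰Y, ¹⁷⁷Lu, ⁶⁷Cu) are
supported, mirroring the study's isotope groupings.

### Fidelity statement and problem sizes

This engine reproduces the *qualitative* behaviour of the full-physics
study — positive enhancement for compact clusters, decay of the effect
with separation distance, vanishing enhancement beyond a few hundred
nm, alpha emitters dominating the near-surface radial dose, higher Auger
production in compact clusters — but **not** the printed magnitudes
(e.g. a ~21 % total-dose increase): with the simplified cross-sections
the engine's DE at SD = 1 nm is of order +1–2 %.  Tests therefore assert
signs, orderings and convergences with batch-based 3σ statistics.

Problem sizes in the test suite are desk-scale by design: hundreds to a
few thousand histories per condition (DE positivity at SD = 1 nm: three cluster realizations ×
2000 histories; the distance trend: 600 histories × 8 batches per
separation; dispersed separations: 120 histories in the
100 µm phantom where each alpha stops fully; Auger comparison: 3000
histories per arm in a 10 µm phantom, since Auger production is local to
the cluster; radial profiles: 150 histories per isotope; conservation
check: 10⁴ mixed histories).  The synthetic emission fixtures and the
monoenergetic 5.9 MeV alpha test source (the hardest alpha line of the
²²³Ra chain) isolate transport properties from decay-sampling variance.

### What the synthetic conditions do not show

The generator emulates the stated study conditions (counts, sizes,
activities, cuts); it does not emulate evaluated cross-section detail,
track-structure physics, recoil transport, coherent scattering, or
chemistry-stage effects.  Passing tests demonstrate internal consistency
and the qualitative cluster physics, not dosimetric accuracy for real
nanoparticle systems.

## Known limitations

* Sub-keV stopping is an empirical extension; all nanoscale magnitudes
  inherit its uncertainty.
* The 1/ε² transfer spectrum underestimates inner-shell ionization
  structure; Auger yields are indicative only.
* Compton angular correlation is ignored; photon transport matters
  little in µm-scale phantoms but would be wrong in cm-scale ones.
* Radial doses scaled to the full Ã reach 10¹³–10¹⁴ Gy in the first
  shell for alpha chains — arithmetic consequences of nanogram shell
  masses; treat them as relative, not absolute, measures.
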