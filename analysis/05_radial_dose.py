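#!/usr/bin/env python
"""Radial dose around a single radiolabeled nanoparticle.

Decays sampled in the 1 nm radiolabel ring of one particle centred in a
1 um water box; dose in 1 nm shells from the particle surface (8.5 nm)
to 100 nm, scaled to the full cumulative-activity budget of 1 kBq.
Writes results/radial_dose.csv.
"""

from pathlib import Path

import pandas as pd

from nanodose.analysis import THERAPEUTIC_ISOTOPES, run_radial_dose

OUT = Path(__file__).resolve().parents[1] / "results"
N_HISTORIES = 150


def main():
    frames = []
    for iso in THERAPEUTIC_ISOTOPES:
        profile, scale = run_radial_dose(iso, N_HISTORIES, seed=5)
        dose = profile.dose_gy(scale)                    # full 1 kBq budget
        per_meg = profile.dose_gy(1e6 / N_HISTORIES)     # per 1e6 decays
        frames.append(pd.DataFrame({
            "isotope": iso, "r_nm": profile.radii_nm(), "dose_gy": dose,
            "dose_gy_per_1e6_decays": per_meg}))
        print(f"{iso:7s}: first shell {dose[0]:.3e} Gy (full budget), "
              f"{per_meg[0]:.3e} Gy per 1e6 decays")
    OUT.mkdir(exist_ok=True)
    pd.concat(frames).to_csv(OUT / "radial_dose.csv", index=False)
    print("Per decay, the alpha-chain emitters (Bi-213, Ra-223) dominate the "
          "near-surface shells; on the full 1 kBq budget the short-lived "
          "Bi-213 delivers fewer total decays, so its scaled dose drops.")
    print(f"Wrote {OUT / 'radial_dose.csv'}")


if __name__ == "__main__":
    main()
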