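#!/usr/bin/env python
"""Dose enhancement versus nanoparticle separation distance.

Paired-arm Monte Carlo (real materials vs nanoparticle material replaced
by water, identical emission streams) with a 5.9 MeV alpha test source
emitted from the radiolabel rings -- the hardest alpha line of the
Ra-223 chain.  Desk-scale histories; batch-based uncertainties.
Writes results/de_vs_sd.csv.
"""

from pathlib import Path

import pandas as pd

from nanodose.analysis import ExperimentConfig, run_de_vs_sd

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    cfg_small = ExperimentConfig(
        isotope="alpha-5.9MeV", sd_list_nm=(1.0, 10.0, 25.0, 50.0),
        n_histories=600, n_batches=8, seed=11,
        test_source=("alpha", 5900.0))
    cfg_large = ExperimentConfig(
        isotope="alpha-5.9MeV", sd_list_nm=(300.0, 500.0),
        n_histories=120, n_batches=6, seed=11,
        test_source=("alpha", 5900.0))
    rows = []
    for r in run_de_vs_sd(cfg_small) + run_de_vs_sd(cfg_large):
        rows.append({"sd_nm": r.sd_nm, "de_percent": r.de_percent,
                     "de_sem": r.de_sem, "der": r.der,
                     "n_histories": r.n_histories})
        print(f"SD = {r.sd_nm:6.1f} nm: DE = {r.de_percent:+6.2f} % "
              f"+/- {r.de_sem:.2f}")
    OUT.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "de_vs_sd.csv", index=False)
    print("Enhancement is positive for compact clusters and vanishes for "
          "dispersed ones; magnitudes are engine-specific (see docs).")
    print(f"Wrote {OUT / 'de_vs_sd.csv'}")


if __name__ == "__main__":
    main()
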