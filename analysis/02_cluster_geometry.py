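#!/usr/bin/env python
"""Nanoparticle cluster generation across the separation-distance grid.

Packs the default 500-particle cluster at each maximum separation
distance, verifies the non-overlap and gap invariants, and reports the
cluster extent and iron concentration.  Writes
results/cluster_geometry.csv and a CSV export of the SD = 1 nm cluster.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from nanodose.geometry import check_overlaps, fe_concentration, generate_cluster
from nanodose.io import write_cluster_csv

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    rows = []
    OUT.mkdir(exist_ok=True)
    for sd in (0.0, 1.0, 10.0, 25.0, 50.0):
        cl = generate_cluster(n=500, box_nm=3500.0, sd_max_nm=sd, seed=1,
                              n_labeled=10)
        gaps = cl.nearest_neighbor_gaps()
        extent = np.linalg.norm(
            cl.centers_nm - cl.centers_nm.mean(0), axis=1).max()
        rows.append({
            "sd_max_nm": sd,
            "overlaps": len(check_overlaps(cl)),
            "gap_max_nm": gaps.max(),
            "gap_median_nm": np.median(gaps),
            "cluster_radius_nm": extent + cl.outer_radius_nm,
            "fe_mM": fe_concentration(cl),
        })
        print(f"SD={sd:5.1f} nm: radius {rows[-1]['cluster_radius_nm']:6.1f} nm,"
              f" max gap {gaps.max():.3f} nm, overlaps"
              f" {rows[-1]['overlaps']}, [Fe] {rows[-1]['fe_mM']:.4f} mM")
        if sd == 1.0:
            write_cluster_csv(cl, OUT / "cluster_sd1.csv")
    pd.DataFrame(rows).to_csv(OUT / "cluster_geometry.csv", index=False)
    print(f"Wrote {OUT / 'cluster_geometry.csv'}")


if __name__ == "__main__":
    main()
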