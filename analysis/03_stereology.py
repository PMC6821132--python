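#!/usr/bin/env python
"""Stereological total-count estimation on synthetic retinas.

Generates homogeneous retinas (known true counts), samples three fields of
view per region at the three eccentricities, combines them with the
11/33/56% area weights, and compares the estimated totals with the truth
over 50 replicates.  Also shows the weighted-vs-unweighted difference on a
center-dense gradient retina.

Writes results/stereology.csv.
"""

import numpy as np
import pandas as pd

from astroclear import stereology as st
from astroclear.io import write_table
from astroclear.synthetic_data import generate_retina


def main() -> None:
    rows = []
    for seed in range(50):
        pat = generate_retina(1000.0, 1000.0, 2.0, seed=seed)
        samples = st.sample_fields(pat, fov_side=0.25, n_fov_per_region=3,
                                   seed=5000 + seed)
        est = st.total_count(st.weighted_mean_density(samples), pat.total_area)
        rows.append({"seed": seed, "true_count": pat.true_count, "estimate": est})
    df = pd.DataFrame(rows)
    write_table(df, "results/stereology.csv")
    ratio = df["estimate"].mean() / df["true_count"].mean()
    print(f"homogeneous retinas: mean estimate / mean truth = {ratio:.4f} "
          f"over {len(df)} replicates")

    # gradient retina: the area weights down-weight the dense centre
    pat = generate_retina(2000.0, 400.0, 2.0, seed=99)
    samples = st.sample_fields(pat, fov_side=0.25, n_fov_per_region=3, seed=100)
    weighted = st.weighted_mean_density(samples)
    naive = float(np.mean([samples[r].mean for r in st.REGIONS]))
    print(f"gradient retina: weighted density {weighted:.0f} vs naive mean "
          f"{naive:.0f} cells/mm^2 (weights suppress the dense centre)")


if __name__ == "__main__":
    main()
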