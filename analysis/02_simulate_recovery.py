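#!/usr/bin/env python
"""Stochastic death-and-clearance simulation and clearance-time recovery.

Simulates an RGC-like decline (100,000 cells, 5.22%/day loss, 2.47-hour
corpse visibility, 10 days) under both corpse-lifetime models, checks the
quasi-steady-state relation D ~ d*V/24, and recovers the clearance time
from snapshots alone over 20 replicate seeds.

Writes results/snapshots_seed0.csv and results/recovery.csv.
"""

import numpy as np
import pandas as pd

from astroclear.io import write_table
from astroclear.synthetic_data import (
    DeathSimConfig,
    recover_clearance_time,
    simulate_death_process,
)

S0, D_DAY, V_TRUE, N_DAYS = 100_000, 0.0522, 2.47, 10


def main() -> None:
    cfg0 = DeathSimConfig(S0=S0, per_day_loss=D_DAY, clearance_hours=V_TRUE,
                          n_days=N_DAYS, seed=0)
    s = simulate_death_process(cfg0)
    write_table(pd.DataFrame({
        "day": s.days, "live": s.live, "visible": s.visible_corpses,
        "cleared": s.cleared_cumulative, "fraction": s.observed_fraction,
    }), "results/snapshots_seed0.csv", config=cfg0.__dict__)
    print(f"quasi-steady state: mean observed fraction "
          f"{s.observed_fraction.mean():.6f} vs d*V/24 = {D_DAY * V_TRUE / 24:.6f}")

    rows = []
    for model in ("fixed", "exponential"):
        vhats = []
        for seed in range(20):
            cfg = DeathSimConfig(S0=S0, per_day_loss=D_DAY, clearance_hours=V_TRUE,
                                 n_days=N_DAYS, seed=seed,
                                 corpse_lifetime_model=model)
            vhats.append(recover_clearance_time(simulate_death_process(cfg)))
        med = float(np.median(vhats))
        rows.append({"lifetime_model": model, "V_true_hours": V_TRUE,
                     "V_recovered_median": med,
                     "relative_error": med / V_TRUE - 1.0})
        print(f"{model:12s} median recovered V = {med:.3f} h "
              f"({100 * (med / V_TRUE - 1):+.1f}% vs truth {V_TRUE} h)")
    write_table(pd.DataFrame(rows), "results/recovery.csv")


if __name__ == "__main__":
    main()
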