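#!/usr/bin/env python
"""Shadow-matrix MSE co-localization ranking of lipid tails vs nanoparticles.

Two studies on synthetic membranes:

1. Default heterogeneous composition: ranks every tail type (and the
   sterol) by mean MSE against the nanoparticle shadow.  The sterol,
   planted anti-correlated with the target domains and abundant, ranks
   last by a wide margin — the ranking's most robust feature.  Among
   tails the raw MSE mixes abundance with co-localization.
2. Abundance-controlled composition (four tail species at equal copy
   number): with planted strength 0.9 the DA target ranks first in
   essentially every seed; with strength 0 the first rank is uniform.

Writes results/colocalization_default.csv and
results/colocalization_recovery.csv.
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from memshadow import experiments as E
from memshadow.colocalization import colocalization_table, default_targets
from memshadow.synthetic_membrane import MembraneSpec, build_membrane
from memshadow.trajectory_io import residue_bead_labels

warnings.filterwarnings("ignore")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    root = Path(__file__).resolve().parents[1]
    (root / "results").mkdir(exist_ok=True)

    spec = MembraneSpec(seed=args.seed, n_frames=4)
    traj, truth = build_membrane(spec)
    table = colocalization_table(
        traj,
        residue_bead_labels(traj[0], "NP"),
        default_targets(spec.composition, traj[0]),
    )
    table.to_csv(root / "results" / "colocalization_default.csv", index=False)
    print("default composition, mean MSE vs nanoparticles (ascending):")
    print(table[["species", "mean_mse", "se_mse", "rank"]].round(4).to_string(index=False))
    print(f"planted target: {truth.colocal_target} "
          f"(strength {truth.colocal_strength}); sterol ranks "
          f"{int(table.loc[table.species == 'CHOL', 'rank'].iloc[0])} of {len(table)}")

    rec = E.colocal_recovery(n_seeds=20, seed=args.seed)
    null = E.colocal_null(n_seeds=200, seed=args.seed)
    summary = pd.DataFrame(
        [
            {"study": "strength 0.9, equal abundance",
             "metric": "target first-rank fraction",
             "value": rec["first_rank_fraction"], "n_seeds": rec["n"]},
            {"study": "strength 0.0, equal abundance",
             "metric": "first-rank uniformity chi2 p",
             "value": null["chi2_p"], "n_seeds": null["n"]},
        ]
    )
    summary.to_csv(root / "results" / "colocalization_recovery.csv", index=False)
    print("\nabundance-controlled studies:")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
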