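#!/usr/bin/env python
"""Monte-Carlo benchmark of decoupled-set recovery and null calibration.

For each decoupling factor δ in {0.2, 0.6, 1.0} simulates replicate
cohorts and measures how often the ΔΣR ranking places the three planted
decoupled piRNAs in its top-3. δ=1 doubles as the null: there it also
measures the flag rate of the partner-paired t-test at p < 1e-3 and the
DE screen at q <= 0.05.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from pirna_coreg import coexpression as cx
from pirna_coreg import group_stats as gs
from pirna_coreg import simulate as sim

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--replicates", type=int, default=100)
parser.add_argument("--out", type=Path, default=Path("results/recovery_benchmark.tsv"))
args = parser.parse_args()

reference = sim.make_reference(38, seed=args.seed)
rows = []
for delta in (0.2, 0.6, 1.0):
    fracs, full, flag_rates, de_counts = [], 0, [], []
    for rep in range(args.replicates):
        cfg = sim.SimulationConfig(decoupling_factor=delta,
                                   seed=args.seed * 100_000 + rep)
        _, rpkm, truth = sim.simulate_expression(cfg, reference)
        ca = cx.pearson_matrix(rpkm, "A")
        cb = cx.pearson_matrix(rpkm, "B")
        scores = cx.delta_sum_r(cx.sum_r(ca), cx.sum_r(cb))
        rec = sim.evaluate_recovery(scores, truth, 3)
        fracs.append(rec["fraction"])
        full += rec["fraction"] == 1.0
        if delta == 1.0:
            flag_rates.append(cx.coreg_scores(ca, cb)["flagged"].mean())
            de_counts.append(gs.per_feature_group_test(rpkm)["flagged"].sum())
    rows.append({
        "delta": delta,
        "mean_recovered_fraction": np.mean(fracs),
        "all3_in_top3_rate": full / args.replicates,
    })
    print(f"delta={delta}: mean recovered fraction {np.mean(fracs):.3f}, "
          f"all-3-in-top-3 in {100 * full / args.replicates:.1f}% of replicates")

print(f"\nnull (delta=1) calibration over {args.replicates} replicates:")
print(f"  paired-test flag rate at p<1e-3: {100 * np.mean(flag_rates):.2f}% "
      "(anti-conservative under the co-expression block; see docs/methods.md)")
print(f"  DE screen flags per replicate: {np.mean(de_counts):.2f} (expected ~0)")

args.out.parent.mkdir(parents=True, exist_ok=True)
pd.DataFrame(rows).to_csv(args.out, sep="\t", index=False)
print(f"written to {args.out}")
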