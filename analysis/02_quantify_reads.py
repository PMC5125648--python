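#!/usr/bin/env python
"""Small-RNA quantification demonstration on simulated reads.

Simulates a small bimodal read set (22 nt miRNA-like and 29 nt piRNA-like
inserts plus 3' adapter), trims, calls the length-distribution peaks,
assigns reads back to the reference by exact match and verifies that the
recovered count matrix equals the simulated one cell for cell.
"""

import argparse
from pathlib import Path

from pirna_coreg import quantify
from pirna_coreg import simulate as sim
from pirna_coreg.reference import PiRNARecord, PiRNAReference

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--outdir", type=Path, default=Path("results/quantify"))
args = parser.parse_args()

short = sim.make_reference(7, (22, 22), seed=args.seed)
long_ = sim.make_reference(5, (29, 29), seed=args.seed + 1)
reference = PiRNAReference(
    list(short.records)
    + [PiRNARecord(f"sim_piR_{i + 8:06d}", r.sequence)
       for i, r in enumerate(long_.records)])

cfg = sim.SimulationConfig(n_features=12, n_modules=1, module_size=6,
                           decoupled_set_size=2, n_samples_per_group=3,
                           library_size=2000, seed=args.seed)
counts, _, _ = sim.simulate_expression(cfg, reference)
adapter = sim.TRUSEQ_SMALL_RNA_ADAPTER
reads = sim.simulate_reads(counts, reference, adapter, seed=args.seed)

trimmed = {s: [quantify.trim_adapter(r, adapter) for r in rs]
           for s, rs in reads.items()}
hist = quantify.length_histogram([r for rs in trimmed.values() for r in rs])
peaks = quantify.find_peaks(hist)
assigned = quantify.assign_reads(trimmed, reference)
rpkm = quantify.rpkm(assigned, reference)

args.outdir.mkdir(parents=True, exist_ok=True)
sim.write_fastq(reads, args.outdir / "reads")
hist.write(args.outdir / "length_histogram.tsv")
assigned.counts.to_csv(args.outdir / "counts_recovered.tsv", sep="\t")

exact = (assigned.counts.to_numpy() == counts.values.to_numpy()).all()
total = int(sum(len(rs) for rs in reads.values()))
print(f"{total} reads simulated across {len(reads)} samples")
print(f"trimmed length peaks: {sorted(peaks)} nt (expected bimodal 22/29)")
print(f"unassigned: {int(assigned.unassigned.sum())}, "
      f"ambiguous: {int(assigned.ambiguous.sum())}")
print(f"count matrix recovered exactly: {bool(exact)}")
print(f"written to {args.outdir}/")
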