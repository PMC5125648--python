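"""Minimal small-RNA quantification.

Adapter trimming, read-length histogram with peak calling, exact-match
assignment of trimmed reads to a piRNA reference, and RPKM computation.
Exact dictionary matching deliberately replaces a genome aligner: the
analyses downstream consume only the per-piRNA abundance table, and the
simulator emits reads whose inserts are exact reference sequences.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import CountMatrix, ExpressionMatrix
from .reference import PiRNAReference

__all__ = [
    "trim_adapter",
    "length_histogram",
    "find_peaks",
    "assign_reads",
    "rpkm",
    "read_share",
    "LengthHistogram",
    "MIN_ADAPTER_MATCH",
]

log = logging.getLogger(__name__)

#: Minimum adapter prefix length that counts as an adapter hit; standard
#: small-RNA trimming practice (shorter matches arise by chance too often).
MIN_ADAPTER_MATCH = 8


def trim_adapter(read: str, adapter: str, min_match: int = MIN_ADAPTER_MATCH) -> str:
    """Truncate *read* at the first occurrence of an adapter prefix.

    A position qualifies when the read, from that position to its end or to
    the adapter's end (whichever comes first), equals the corresponding
    adapter prefix exactly, and the matched prefix is at least *min_match*
    nt long (the whole adapter when it is shorter than *min_match*). Reads
    with no qualifying position are returned unchanged; the result is never
    longer than the input.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    need = min(min_match, len(adapter))
    for pos in range(0, len(read) - need + 1):
        m = min(len(adapter), len(read) - pos)
        if read[pos:pos + m] == adapter[:m]:
            return read[:pos]
    return read


@dataclass
class LengthHistogram:
    """Read counts by exact (trimmed) length."""

    counts: dict[int, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def as_series(self) -> pd.Series:
        if not self.counts:
            return pd.Series(dtype=int)
        lo, hi = min(self.counts), max(self.counts)
        return pd.Series({L: self.counts.get(L, 0) for L in range(lo, hi + 1)},
                         name="reads").rename_axis("length_nt")

    def write(self, path) -> None:
        self.as_series().to_csv(path, sep="\t", header=True)


def length_histogram(reads) -> LengthHistogram:
    """Tally trimmed reads by exact length."""
    return LengthHistogram(dict(Counter(len(r) for r in reads)))


def find_peaks(hist: LengthHistogram, window: int = 1, top: int = 2) -> list[int]:
    """Local maxima of the length distribution, strongest first.

    A length is a peak when its count exceeds every other bin within
    ±*window* (ties broken toward the smaller length). At most *top* peaks
    are returned, sorted by count descending. The bimodal small-RNA
    signature (a miRNA peak near 22 nt and a piRNA peak near 29 nt) shows
    up as the top two peaks.
    """
    if hist.total == 0:
        raise ValueError("cannot find peaks of an empty histogram")
    counts = hist.counts

    def beats(L: int) -> bool:
        c = counts.get(L, 0)
        if c == 0:
            return False
        for other in range(L - window, L + window + 1):
            if other == L:
                continue
            oc = counts.get(other, 0)
            if oc > c or (oc == c and other < L):
                return False
        return True

    peaks = [L for L in sorted(counts) if beats(L)]
    peaks.sort(key=lambda L: (-counts[L], L))
    return peaks[:top]


def assign_reads(reads_by_sample: dict, reference: PiRNAReference) -> CountMatrix:
    """Assign trimmed reads to reference features by exact sequence match.

    A read increments feature *i* iff it equals reference sequence *i*
    exactly. Reads matching no sequence are tallied as unassigned. Should
    several reference records share one sequence, their reads are assigned
    to the lexicographically smallest id, tallied as ambiguous, and a
    warning is logged.
    """
    lookup: dict[str, list[str]] = {}
    for rec in reference:
        lookup.setdefault(rec.sequence, []).append(rec.id)
    dup_seqs = {s: ids for s, ids in lookup.items() if len(ids) > 1}
    if dup_seqs:
        log.warning("reference contains %d duplicated sequences; ambiguous reads "
                    "will be assigned to the lexicographically smallest id",
                    len(dup_seqs))

    samples = list(reads_by_sample)
    counts = pd.DataFrame(0, index=pd.Index(reference.ids, name="feature"),
                          columns=samples, dtype=int)
    unassigned = pd.Series(0, index=samples, dtype=int)
    ambiguous = pd.Series(0, index=samples, dtype=int)
    for sample, reads in reads_by_sample.items():
        for read in reads:
            ids = lookup.get(read)
            if ids is None:
                unassigned[sample] += 1
            else:
                counts.loc[min(ids), sample] += 1
                if len(ids) > 1:
                    ambiguous[sample] += 1
    return CountMatrix(counts, unassigned, ambiguous)


def rpkm(counts: CountMatrix | pd.DataFrame, reference: PiRNAReference,
         library_sizes: pd.Series | dict | None = None,
         groups: pd.Series | None = None, controls=frozenset()) -> ExpressionMatrix:
    """Reads Per Kilobase of feature per Million mapped reads.

    RPKM(i, s) = count(i, s) * 1e9 / (length_i [nt] * library_size_s).
    *library_sizes* defaults to the per-sample totals of assigned reads.
    """
    table = counts.counts if isinstance(counts, CountMatrix) else counts
    if library_sizes is None:
        library_sizes = table.sum(axis=0)
    lib = pd.Series(library_sizes).astype(float).loc[list(table.columns)]
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise ValueError(f"library size must be positive; offending samples: {bad}")
    lengths = reference.lengths()
    missing = [f for f in table.index if f not in lengths]
    if missing:
        raise ValueError(f"no reference length for features: {missing}")
    length_nt = pd.Series({f: lengths[f] for f in table.index}, dtype=float)
    values = table.astype(float).mul(1e9).div(length_nt, axis=0).div(lib, axis=1)
    return ExpressionMatrix(values, "RPKM", groups=groups, controls=controls)


def read_share(E: ExpressionMatrix, reference: PiRNAReference) -> pd.Series:
    """Per-feature share of the total signal on the read scale.

    RPKM is length-normalised; multiplying back by feature length recovers
    a quantity proportional to read counts, so the shares answer "what
    fraction of all piRNA reads does each piRNA cover". For a counts
    matrix the shares are computed directly. Summed over all samples.
    """
    lengths = reference.lengths()
    missing = [f for f in E.features if f not in lengths]
    if missing:
        raise ValueError(f"no reference length for features: {missing}")
    totals = E.values.sum(axis=1)
    if E.unit == "RPKM":
        totals = totals * pd.Series({f: lengths[f] for f in E.features}, dtype=float)
    return totals / totals.sum()
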