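"""Two-group piRNA expression simulator with known co-regulation structure.

The generative model is a single-factor-per-module Gaussian latent factor
model on log2 abundance:

    log2 a_{is} = mu_i + lambda_{i,g(s)} * f_{k(i),s} + eps_{is}

where f_{k,s} ~ N(0,1) is one shared factor per (module k, sample s),
eps_{is} ~ N(0, sigma^2) is residual noise and mu_i ~ N(m0, s0^2) sets the
baseline level of feature i. Members of one module are thus block-correlated,
which is exactly what the correlation-matrix analysis downstream measures.
Decoupling — the generative analogue of "less tightly regulated
co-expression" — attenuates the loading of a chosen subset of module members
in group A only (lambda -> delta * lambda, 0 <= delta <= 1), leaving the
expression *level* mu_i untouched: group A loses correlation tightness
without any differential expression.

Counts are Poisson draws with per-sample means proportional to 2^a scaled to
the target library size; RPKM is then computed from the counts through the
quantification module, as in the real pipeline.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import quantify
from .matrix import CountMatrix, ExpressionMatrix
from .reference import MAX_PIRNA_LEN, MIN_PIRNA_LEN, PiRNARecord, PiRNAReference

__all__ = [
    "SimulationConfig",
    "SimTruth",
    "TRUSEQ_SMALL_RNA_ADAPTER",
    "make_reference",
    "simulate_expression",
    "simulate_reads",
    "write_fastq",
    "evaluate_recovery",
]

#: Illumina TruSeq small RNA 3' adapter, the library chemistry the read
#: simulator emulates.
TRUSEQ_SMALL_RNA_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

GROUP_A = "A"  # RA-like: decoupled features lose factor loading here
GROUP_B = "B"  # OA-like: coupling intact


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic two-group cohort.

    Defaults mirror the sequencing arm of the study being emulated: 38
    piRNAs passing the abundance filter, 9 samples per group, one
    co-regulated module of 12 piRNAs of which 3 are decoupled in the
    RA-like group.
    """

    n_features: int = 38
    n_samples_per_group: int = 9
    n_modules: int = 1
    module_size: int = 12
    loading: float = 1.2            # lambda, log2-scale factor loading when coupled
    decoupling_factor: float = 0.2  # delta, multiplier on lambda in group A
    decoupled_set_size: int = 3
    baseline_log_mean: float = 10.0  # log2 scale; see docs/methods.md
    baseline_log_sd: float = 1.5
    noise_sd: float = 0.5            # sigma, residual log2-scale sd
    library_size: int = 1_000_000    # target reads per sample
    library_size_jitter: float = 0.0  # uniform +/- fraction, e.g. 0.2
    nb_dispersion: float | None = None  # optional NB overdispersion (None = Poisson)
    seed: int = 0

    def validate(self) -> None:
        if self.n_features < 1 or self.n_samples_per_group < 1:
            raise ValueError("n_features and n_samples_per_group must be >= 1")
        if self.n_modules * self.module_size > self.n_features:
            raise ValueError("n_modules * module_size exceeds n_features")
        if self.decoupled_set_size > self.module_size:
            raise ValueError("decoupled_set_size exceeds module_size")
        if not 0.0 <= self.decoupling_factor <= 1.0:
            raise ValueError("decoupling_factor must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if not 0.0 <= self.library_size_jitter < 1.0:
            raise ValueError("library_size_jitter must lie in [0, 1)")


@dataclass
class SimTruth:
    """Ground truth emitted with every simulated cohort."""

    module_of: dict[str, int | None]
    decoupled: frozenset
    effective_loading: pd.DataFrame  # features x groups {A, B}

    def __post_init__(self) -> None:
        self.decoupled = frozenset(self.decoupled)
        in_module = {f for f, m in self.module_of.items() if m is not None}
        if not self.decoupled <= in_module:
            raise ValueError("decoupled features must belong to a module")

    def to_frame(self) -> pd.DataFrame:
        feats = list(self.module_of)
        return pd.DataFrame({
            "module": [self.module_of[f] if self.module_of[f] is not None else -1
                       for f in feats],
            "decoupled": [f in self.decoupled for f in feats],
            "loading_A": self.effective_loading.loc[feats, GROUP_A].to_numpy(),
            "loading_B": self.effective_loading.loc[feats, GROUP_B].to_numpy(),
        }, index=pd.Index(feats, name="feature"))


def make_reference(n_features: int, length_range: tuple[int, int] = (26, 32),
                   seed: int = 0,
                   avoid_motif: str | None = TRUSEQ_SMALL_RNA_ADAPTER[:quantify.MIN_ADAPTER_MATCH],
                   ) -> PiRNAReference:
    """Random piRNA reference with unique ids ``sim_piR_000001`` ...

    Lengths are uniform over *length_range* (inclusive). Sequences are
    uniform over {A,C,G,T}, redrawn when they duplicate an earlier sequence
    or contain *avoid_motif* — a sequence containing the adapter's match
    prefix is indistinguishable from adapter read-through, so the simulator
    keeps the reference free of that ambiguity.
    """
    lo, hi = length_range
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    if not (MIN_PIRNA_LEN <= lo <= hi <= MAX_PIRNA_LEN):
        raise ValueError(
            f"length range [{lo}, {hi}] violates {MIN_PIRNA_LEN} <= min <= max <= {MAX_PIRNA_LEN}"
        )
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGT"))
    records, seen = [], set()
    for i in range(1, n_features + 1):
        while True:
            L = int(rng.integers(lo, hi + 1))
            seq = "".join(rng.choice(alphabet, size=L))
            if seq in seen or (avoid_motif and avoid_motif in seq):
                continue
            break
        seen.add(seq)
        records.append(PiRNARecord(f"sim_piR_{i:06d}", seq))
    return PiRNAReference(records)


def _draw_log2_abundance(config: SimulationConfig, rng: np.random.Generator,
                         features: list[str]):
    """Latent-factor draw; returns (log2 abundance array, SimTruth, samples, groups)."""
    p, n = config.n_features, config.n_samples_per_group
    samples = [f"{GROUP_A}{j + 1}" for j in range(n)] + [f"{GROUP_B}{j + 1}" for j in range(n)]
    group_of = np.array([GROUP_A] * n + [GROUP_B] * n)

    module_of: dict[str, int | None] = {f: None for f in features}
    for k in range(config.n_modules):
        for f in features[k * config.module_size:(k + 1) * config.module_size]:
            module_of[f] = k
    # decoupled set: first decoupled_set_size members of module 0
    decoupled = frozenset(features[:config.decoupled_set_size]) if config.n_modules else frozenset()

    lam = np.zeros((p, 2))  # columns: group A, group B
    for i, f in enumerate(features):
        if module_of[f] is not None:
            lam[i, 1] = config.loading
            lam[i, 0] = config.loading * (config.decoupling_factor if f in decoupled else 1.0)
    eff = pd.DataFrame(lam, index=pd.Index(features, name="feature"),
                       columns=[GROUP_A, GROUP_B])

    mu = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=p)
    factors = rng.standard_normal((max(config.n_modules, 1), 2 * n))
    eps = rng.normal(0.0, config.noise_sd, size=(p, 2 * n))

    a = mu[:, None] + eps
    g_idx = (group_of == GROUP_B).astype(int)
    for i, f in enumerate(features):
        k = module_of[f]
        if k is not None:
            a[i] += lam[i, g_idx] * factors[k]
    truth = SimTruth(module_of, decoupled, eff)
    return a, truth, samples, group_of


def simulate_expression(config: SimulationConfig, reference: PiRNAReference,
                        ) -> tuple[ExpressionMatrix, ExpressionMatrix, SimTruth]:
    """Simulate a two-group cohort; returns (counts, RPKM, truth).

    Deterministic for a fixed ``config.seed``. The RPKM table is produced
    from the simulated counts by the quantification module's ``rpkm``
    operation, exactly as real counts would be.
    """
    config.validate()
    if len(reference) < config.n_features:
        raise ValueError(f"reference has {len(reference)} records, "
                         f"need >= {config.n_features}")
    rng = np.random.default_rng(config.seed)
    features = reference.ids[:config.n_features]
    a, truth, samples, group_of = _draw_log2_abundance(config, rng, features)

    abundance = np.exp2(a)
    lib = np.full(len(samples), float(config.library_size))
    if config.library_size_jitter:
        lib *= rng.uniform(1 - config.library_size_jitter,
                           1 + config.library_size_jitter, size=len(samples))
    # Scale by a cohort-wide constant (not per-sample sums): column sums land
    # near the library size without closing the composition over the
    # simulated features. In a real library the "million mapped reads"
    # denominator is dominated by non-piRNA reads, so per-piRNA RPKM is not
    # a closed composition either; per-sample renormalisation here would
    # induce spurious negative correlations between module and background
    # features and bury the decoupling signal.
    scale = 1.0 / abundance.sum(axis=0).mean()
    lam_pois = abundance * scale * lib
    if config.nb_dispersion:
        # NB as Gamma-Poisson mixture with shape 1/dispersion
        shape = 1.0 / config.nb_dispersion
        lam_pois = rng.gamma(shape, lam_pois / shape)
    count_arr = rng.poisson(lam_pois)

    groups = pd.Series(group_of, index=samples)
    counts_df = pd.DataFrame(count_arr, index=pd.Index(features, name="feature"),
                             columns=samples)
    counts = ExpressionMatrix(counts_df.astype(float), "counts", groups=groups)
    # RPKM against the known per-sample mapped totals (the externally
    # supplied denominator of the quantification module), mirroring a real
    # pipeline where "million mapped reads" counts the whole library.
    rpkm_mat = quantify.rpkm(counts_df, reference,
                             library_sizes=pd.Series(lib, index=samples),
                             groups=groups)
    return counts, rpkm_mat, truth


def simulate_reads(counts: ExpressionMatrix, reference: PiRNAReference,
                   adapter: str = TRUSEQ_SMALL_RNA_ADAPTER, seed: int = 0,
                   read_length: int = 50) -> dict[str, list[str]]:
    """Expand a count matrix into per-sample reads (insert + adapter).

    Each read is the feature's reference sequence followed by the 3'
    adapter, truncated at *read_length*; each count-matrix cell contributes
    exactly that many identical reads, shuffled within the sample. Fixed
    seed gives a byte-identical result.
    """
    missing = [f for f in counts.features if f not in reference]
    if missing:
        raise ValueError(f"features absent from reference: {missing}")
    rng = np.random.default_rng(seed)
    reads_by_sample: dict[str, list[str]] = {}
    for sample in counts.samples:
        reads: list[str] = []
        for f in counts.features:
            n = int(round(counts.values.at[f, sample]))
            if n:
                read = (reference[f].sequence + adapter)[:read_length]
                reads.extend([read] * n)
        rng.shuffle(reads)
        reads_by_sample[sample] = reads
    return reads_by_sample


def write_fastq(reads_by_sample: dict[str, list[str]], outdir,
                prefix: str = "sample") -> dict[str, Path]:
    """Write one Phred+33 FASTQ per sample (constant quality 'I')."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for sample, reads in reads_by_sample.items():
        path = outdir / f"{prefix}_{sample}.fastq"
        with open(path, "w") as fh:
            for i, read in enumerate(reads, start=1):
                fh.write(f"@{sample}_read_{i}\n{read}\n+\n{'I' * len(read)}\n")
        paths[sample] = path
    return paths


def read_fastq(path) -> list[str]:
    """Read sequences from a (optionally gzipped) FASTQ file."""
    opener = gzip.open if str(path).endswith(".gz") else open
    reads = []
    with opener(str(path), "rt") as fh:
        for i, line in enumerate(fh):
            if i % 4 == 1:
                reads.append(line.strip())
    return reads


def evaluate_recovery(scores: pd.DataFrame, truth: SimTruth, k: int) -> dict:
    """How much of the decoupled set lands in the top-k of the ΔΣR ranking.

    *scores* must carry a ``rank`` column (1 = largest ΔΣR). Returns the
    recovered fraction (NaN when the truth has no decoupled features) and
    the rank of every decoupled feature.
    """
    if k > len(scores):
        raise ValueError(f"k={k} exceeds the {len(scores)} scored features")
    missing = set(truth.module_of) - set(scores.index)
    extra = set(scores.index) - set(truth.module_of)
    if missing or extra:
        raise ValueError(f"feature universes differ (missing={sorted(missing)}, "
                         f"extra={sorted(extra)})")
    ranks = {f: int(scores.at[f, "rank"]) for f in sorted(truth.decoupled)}
    if not truth.decoupled:
        return {"fraction": float("nan"), "ranks": ranks, "k": k}
    hits = sum(1 for r in ranks.values() if r <= k)
    return {"fraction": hits / len(truth.decoupled), "ranks": ranks, "k": k}
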