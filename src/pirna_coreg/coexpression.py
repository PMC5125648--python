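"""Differential co-expression ("co-regulation tightness") analysis.

Given a two-group RPKM matrix, this module reproduces the correlation-based
comparison at the heart of the study: abundance filtering, per-group Pearson
matrices over the retained piRNAs, the per-feature sum of correlations ΣR
and its between-group difference ΔΣR = ΣR(B) − ΣR(A), the per-pair ΔR
matrix with strength and decoupling flags, a partner-paired t-test per
feature comparing its two correlation vectors, and the global comparison of
per-feature mean correlations. Group A plays the RA-like role and group B
the OA-like role throughout; large positive ΔΣR marks features whose
co-expression is less tightly regulated in group A.

Correlations are computed on raw RPKM by default (an optional ``log2(x+1)``
transform is available), and the endogenous control features are displayed
in the matrices but excluded from every ΣR / test computation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix

__all__ = [
    "GroupCorrelation",
    "filter_expressed",
    "count_expressed_in_all",
    "pearson_matrix",
    "sum_r",
    "delta_sum_r",
    "coreg_scores",
    "delta_r_matrix",
    "sum_delta_r",
    "per_feature_paired_test",
    "global_mean_test",
    "cluster_samples",
    "STRONG_R",
    "MODERATE_R",
    "DECOUPLING_DELTA_R",
    "LOG_P_CUTOFF",
]

log = logging.getLogger(__name__)

STRONG_R = 0.75          # strong positive correlation highlight
MODERATE_R = 0.5         # moderate correlation highlight
DECOUPLING_DELTA_R = 0.5  # |ΔR| at or beyond which a pair is flagged decoupled
LOG_P_CUTOFF = -3.0      # log10 p below which a feature is flagged


@dataclass
class GroupCorrelation:
    """Symmetric Pearson matrix over filtered features for one group."""

    group: str
    r: pd.DataFrame
    n_samples: int

    @property
    def features(self) -> pd.Index:
        return self.r.index


def filter_expressed(E: ExpressionMatrix, min_mean_rpkm: float = 500.0) -> ExpressionMatrix:
    """Retain features whose mean RPKM over all samples (groups pooled)
    reaches *min_mean_rpkm*; control features are always retained. Feature
    order is preserved."""
    if E.unit != "RPKM":
        raise ValueError(f"filter_expressed expects RPKM, got unit {E.unit!r}")
    if E.values.shape[1] < 1:
        raise ValueError("matrix has no samples")
    means = E.values.mean(axis=1)
    keep = [f for f in E.features if means[f] >= min_mean_rpkm or f in E.controls]
    if not [f for f in keep if f not in E.controls]:
        raise ValueError(
            f"no features reach mean RPKM >= {min_mean_rpkm}; lower the threshold"
        )
    return E.subset_features(keep)


def count_expressed_in_all(E: ExpressionMatrix) -> int:
    """Number of features with a nonzero value in every sample."""
    return int((E.values > 0).all(axis=1).sum())


def pearson_matrix(E: ExpressionMatrix, group, log_transform: bool = False) -> GroupCorrelation:
    """Sample Pearson correlation between features across one group's samples.

    Computed on the abundance values as given (``log2(x+1)`` first when
    *log_transform*). Constant features have undefined correlations; their
    off-diagonal entries are NaN sentinels, excluded from downstream sums
    with a logged warning.
    """
    samples = E.samples_of(group)
    if len(samples) < 3:
        raise ValueError(f"group {group!r} has {len(samples)} samples; need >= 3")
    if len(E.features) < 2:
        raise ValueError("need >= 2 features to correlate")
    # C-contiguity pins the BLAS summation order, keeping results
    # bit-identical whether the matrix was computed in memory or re-read
    X = np.ascontiguousarray(E.values[samples].to_numpy(dtype=float))
    if log_transform:
        X = np.log2(X + 1.0)
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((Xc ** 2).sum(axis=1))
    constant = norms == 0
    if constant.any():
        log.warning("group %s: %d constant feature(s) have undefined correlations: %s",
                    group, constant.sum(),
                    list(E.features[constant]))
    norms_safe = np.where(constant, 1.0, norms)
    R = (Xc @ Xc.T) / np.outer(norms_safe, norms_safe)
    R = np.clip(R, -1.0, 1.0)
    R[constant, :] = np.nan
    R[:, constant] = np.nan
    np.fill_diagonal(R, 1.0)
    return GroupCorrelation(group, pd.DataFrame(R, index=E.features, columns=E.features),
                            len(samples))


def _partner_mask(features: pd.Index, exclude) -> np.ndarray:
    return ~features.isin(set(exclude))


def sum_r(corr: GroupCorrelation, exclude=frozenset()) -> pd.DataFrame:
    """Per-feature ΣR and mean R over partner features.

    Partners of feature *i* are every feature j ≠ i not in *exclude* (the
    control set) with a defined correlation; NaN partners shrink the
    partner count. ΣR is reported for control features too (they appear in
    the displayed matrix) but controls never act as partners.
    """
    feats = corr.features
    partners = _partner_mask(feats, exclude)
    if partners.sum() < 2:
        raise ValueError("need >= 2 non-control features")
    R = corr.r.to_numpy(copy=True)
    np.fill_diagonal(R, np.nan)  # self never counts as partner
    R[:, ~partners] = np.nan
    sums = np.nansum(R, axis=1)
    n_partners = (~np.isnan(R)).sum(axis=1)
    means = np.where(n_partners > 0, sums / np.maximum(n_partners, 1), np.nan)
    return pd.DataFrame({"sum_r": sums, "mean_r": means, "n_partners": n_partners},
                        index=feats)


def delta_sum_r(scores_A: pd.DataFrame, scores_B: pd.DataFrame,
                orientation: str = "B_minus_A") -> pd.DataFrame:
    """ΔΣR per feature with a descending ranking.

    The default orientation ΣR(B) − ΣR(A) follows the published convention
    Δ = ΣR(OASF) − ΣR(RASF): positive values mark features less tightly
    co-regulated in the RA-like group A. Ties rank by feature id.
    """
    if set(scores_A.index) != set(scores_B.index):
        only_a = sorted(set(scores_A.index) - set(scores_B.index))
        only_b = sorted(set(scores_B.index) - set(scores_A.index))
        raise ValueError(f"feature universes differ (only in A: {only_a}, only in B: {only_b})")
    if orientation not in ("B_minus_A", "A_minus_B"):
        raise ValueError(f"unknown orientation {orientation!r}")
    b = scores_B.loc[scores_A.index]
    sign = 1.0 if orientation == "B_minus_A" else -1.0
    out = pd.DataFrame({
        "sum_r_A": scores_A["sum_r"],
        "sum_r_B": b["sum_r"],
        "mean_r_A": scores_A["mean_r"],
        "mean_r_B": b["mean_r"],
        "delta_sum_r": sign * (b["sum_r"] - scores_A["sum_r"]),
    }, index=scores_A.index)
    # stable sort on an id-sorted frame => ties broken by feature id
    order = out.loc[sorted(out.index)].sort_values(
        "delta_sum_r", ascending=False, kind="mergesort").index
    out["rank"] = pd.Series(range(1, len(out) + 1), index=order)
    return out


def delta_r_matrix(corr_A: GroupCorrelation, corr_B: GroupCorrelation,
                   orientation: str = "B_minus_A",
                   strong: float = STRONG_R, moderate: float = MODERATE_R,
                   decoupling: float = DECOUPLING_DELTA_R) -> pd.DataFrame:
    """Per-pair ΔR table with strength classes and decoupling flags.

    One row per unordered feature pair (i, j), i < j by id: the two group
    correlations, ΔR (default R_B − R_A), a strength class per group
    (strong: R ≥ 0.75, moderate: 0.5 ≤ R < 0.75, weak otherwise) and a
    decoupling flag — ``decoupled_in_A`` when ΔR ≥ +0.5 (the pair is weaker
    in the RA-like group), ``decoupled_in_B`` when ΔR ≤ −0.5.
    """
    if list(corr_A.features) != list(corr_B.features):
        raise ValueError("correlation matrices cover different feature universes")
    if orientation not in ("B_minus_A", "A_minus_B"):
        raise ValueError(f"unknown orientation {orientation!r}")
    sign = 1.0 if orientation == "B_minus_A" else -1.0

    def strength(r: float) -> str:
        if np.isnan(r):
            return "undefined"
        if r >= strong:
            return "strong"
        if r >= moderate:
            return "moderate"
        return "weak"

    rows = []
    feats = list(corr_A.features)
    for i, j in itertools.combinations(sorted(feats), 2):
        ra = corr_A.r.at[i, j]
        rb = corr_B.r.at[i, j]
        dr = sign * (rb - ra)
        if np.isnan(dr):
            flag = "undefined"
        elif dr >= decoupling:
            flag = "decoupled_in_A"
        elif dr <= -decoupling:
            flag = "decoupled_in_B"
        else:
            flag = "none"
        rows.append((i, j, ra, rb, dr, strength(ra), strength(rb), flag))
    return pd.DataFrame(rows, columns=["feature_i", "feature_j", "r_A", "r_B",
                                       "delta_r", "strength_A", "strength_B", "flag"])


def sum_delta_r(pairs: pd.DataFrame, features, exclude=frozenset()) -> pd.Series:
    """Per-feature ΣΔR: sum of ΔR over its non-control partners.

    With the same exclusion set this equals ΔΣR from :func:`delta_sum_r`
    exactly (the column-sum identity).
    """
    exclude = set(exclude)
    totals = pd.Series(0.0, index=pd.Index(features))
    for _, row in pairs.iterrows():
        i, j, dr = row["feature_i"], row["feature_j"], row["delta_r"]
        if np.isnan(dr):
            continue
        if j not in exclude:
            totals[i] += dr
        if i not in exclude:
            totals[j] += dr
    return totals


def per_feature_paired_test(corr_A: GroupCorrelation, corr_B: GroupCorrelation,
                            feature, exclude=frozenset(),
                            fisher_z: bool = False) -> tuple[float, float, float]:
    """Partner-paired two-tailed t-test of one feature's correlation vectors.

    The feature's correlations with each non-control partner j are matched
    between groups and the differences R_B(i,j) − R_A(i,j) tested against
    zero with a paired t-test: t = mean(d) / (sd(d)/√n). Returns
    (t, p, log10 p). Optionally the correlations are Fisher z-transformed
    first. Zero-variance differences give NaN sentinels with a warning.
    """
    feats = corr_A.features
    if list(feats) != list(corr_B.features):
        raise ValueError("correlation matrices cover different feature universes")
    keep = [j for j in feats if j != feature and j not in set(exclude)]
    ra = corr_A.r.loc[feature, keep].to_numpy(dtype=float)
    rb = corr_B.r.loc[feature, keep].to_numpy(dtype=float)
    ok = ~(np.isnan(ra) | np.isnan(rb))
    ra, rb = ra[ok], rb[ok]
    if len(ra) < 3:
        raise ValueError(f"{feature}: needs >= 3 partner features, has {len(ra)}")
    if fisher_z:
        ra = np.arctanh(np.clip(ra, -1 + 1e-15, 1 - 1e-15))
        rb = np.arctanh(np.clip(rb, -1 + 1e-15, 1 - 1e-15))
    d = rb - ra
    if np.allclose(d.std(ddof=1), 0.0):
        log.warning("%s: zero-variance correlation differences; p undefined", feature)
        return (float("nan"), float("nan"), float("nan"))
    t, p = stats.ttest_rel(rb, ra)
    return (float(t), float(p), float(np.log10(p)))


def coreg_scores(corr_A: GroupCorrelation, corr_B: GroupCorrelation,
                 exclude=frozenset(), orientation: str = "B_minus_A",
                 fisher_z: bool = False,
                 log_p_cutoff: float = LOG_P_CUTOFF) -> pd.DataFrame:
    """Full per-feature score table: ΣR per group, ΔΣR with rank, mean R,
    the partner-paired t-test (raw p, log10 p, BH q) and the raw-p flag at
    the log10 cutoff. Control features are scored but never act as partners."""
    sA = sum_r(corr_A, exclude)
    sB = sum_r(corr_B, exclude)
    out = delta_sum_r(sA, sB, orientation=orientation)
    tests = {f: per_feature_paired_test(corr_A, corr_B, f, exclude, fisher_z)
             for f in out.index}
    out["t_statistic"] = [tests[f][0] for f in out.index]
    out["p_value"] = [tests[f][1] for f in out.index]
    out["log10_p"] = [tests[f][2] for f in out.index]
    pvals = out["p_value"].to_numpy()
    ok = ~np.isnan(pvals)
    q = np.full_like(pvals, np.nan)
    if ok.any():
        q[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
    out["q_value"] = q
    out["flagged"] = out["log10_p"] < log_p_cutoff
    return out


def global_mean_test(meanR_A: pd.Series, meanR_B: pd.Series) -> dict:
    """Paired two-tailed t-test across features of the per-feature mean
    correlations, reporting which group's mean is lower."""
    a = np.asarray(meanR_A, dtype=float)
    b = np.asarray(meanR_B, dtype=float)
    if a.shape != b.shape or len(a) < 3:
        raise ValueError("need equal-length vectors over >= 3 features")
    d = b - a
    if np.allclose(np.std(d, ddof=1), 0.0):
        log.warning("global mean test: zero-variance differences; p undefined")
        return {"t": float("nan"), "p": float("nan"), "direction": "equal"}
    t, p = stats.ttest_rel(b, a)
    if np.mean(a) < np.mean(b):
        direction = "A lower"
    elif np.mean(b) < np.mean(a):
        direction = "B lower"
    else:
        direction = "equal"
    return {"t": float(t), "p": float(p), "direction": direction,
            "mean_A": float(np.mean(a)), "mean_B": float(np.mean(b))}


def cluster_samples(E: ExpressionMatrix) -> dict:
    """Average-linkage clustering of samples on (1 − Pearson) distance.

    A sanity check mirroring the unsupervised-clustering question: can the
    expression profiles alone separate the two groups? Returns the linkage,
    a flat 2-cluster cut and the adjusted Rand index against the true
    labels (≈ 0 means the groups are indistinguishable, 1 means a perfect
    split).
    """
    if len(E.samples) < 4:
        raise ValueError("need >= 4 samples to cluster")
    X = E.values.to_numpy(dtype=float).T  # samples x features
    R = np.corrcoef(X)
    if np.isnan(R).any():
        raise ValueError("degenerate distances: constant sample profile")
    D = 1.0 - R
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    labels = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    ari = float("nan")
    if E.groups is not None:
        ari = float(adjusted_rand_score(list(E.groups), list(labels)))
    return {"linkage": Z, "labels": pd.Series(labels, index=E.samples),
            "ari": ari}
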