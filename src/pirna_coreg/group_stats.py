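"""Auxiliary two-group statistics.

A simplified per-feature differential-expression screen (Wilcoxon rank-sum
with Benjamini–Hochberg adjustment) and the comparative-threshold-cycle
(dCt) qPCR utility. The DE screen deliberately does not attempt to
reproduce a negative-binomial GLM pipeline; it exists so the analysis runs
end to end and so the expected *null* outcome — decoupled co-expression
without differential expression — can be demonstrated on synthetic data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrix import ExpressionMatrix

__all__ = ["per_feature_group_test", "qpcr_relative_expression", "fold_change", "QpcrRecord"]

log = logging.getLogger(__name__)


def per_feature_group_test(E: ExpressionMatrix, method: str = "wilcoxon",
                           q_cutoff: float = 0.05) -> pd.DataFrame:
    """Per-feature two-sided two-group test with BH adjustment.

    ``method="wilcoxon"`` (rank-sum, the robust default for skewed RPKM) or
    ``"t"`` (Welch). Returns group means, the statistic, raw p, BH q and a
    flag at ``q <= q_cutoff``.
    """
    groups = E.group_labels()
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    ga, gb = groups
    cols_a, cols_b = E.samples_of(ga), E.samples_of(gb)
    if min(len(cols_a), len(cols_b)) < 3:
        raise ValueError("each group needs >= 3 samples")
    A = E.values[cols_a].to_numpy(dtype=float)
    B = E.values[cols_b].to_numpy(dtype=float)
    stat = np.empty(len(E.features))
    p = np.empty(len(E.features))
    for i in range(len(E.features)):
        if method == "wilcoxon":
            # exact null distribution at cohort scale unless ties force the
            # tie-corrected normal approximation
            vals = np.concatenate([A[i], B[i]])
            exact_ok = (len(vals) <= 50 and len(np.unique(vals)) == len(vals))
            res = stats.mannwhitneyu(A[i], B[i], alternative="two-sided",
                                     method="exact" if exact_ok else "asymptotic")
        elif method == "t":
            res = stats.ttest_ind(A[i], B[i], equal_var=False)
        else:
            raise ValueError(f"unknown method {method!r}")
        stat[i], p[i] = res.statistic, res.pvalue
    p = np.nan_to_num(p, nan=1.0)
    q = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame({
        f"mean_{ga}": A.mean(axis=1),
        f"mean_{gb}": B.mean(axis=1),
        "statistic": stat,
        "p_value": p,
        "q_value": q,
    }, index=E.features)
    out["flagged"] = out["q_value"] <= q_cutoff
    n_flagged = int(out["flagged"].sum())
    log.info("DE screen (%s + BH): %d/%d features at q <= %g "
             "[simplified rank-sum stand-in, not an NB GLM]",
             method, n_flagged, len(out), q_cutoff)
    return out


@dataclass(frozen=True)
class QpcrRecord:
    ct_target: float
    ct_housekeeping: float

    @property
    def dct(self) -> float:
        return self.ct_target - self.ct_housekeeping

    @property
    def relative_expression(self) -> float:
        # higher dCt = later amplification = lower expression
        return float(2.0 ** (-self.dct))


def qpcr_relative_expression(ct_target: float, ct_housekeeping: float) -> QpcrRecord:
    """Comparative threshold-cycle record: dCt = Ct(target) − Ct(housekeeping),
    relative expression 2^(−dCt)."""
    if not (np.isfinite(ct_target) and np.isfinite(ct_housekeeping)):
        raise ValueError("cycle values must be finite")
    return QpcrRecord(float(ct_target), float(ct_housekeeping))


def fold_change(dct_condition: float, dct_reference: float) -> float:
    """2^(−ddCt) with ddCt = dCt(condition) − dCt(reference); values above 1
    mean the condition expresses the target more than the reference."""
    return float(2.0 ** (-(dct_condition - dct_reference)))
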