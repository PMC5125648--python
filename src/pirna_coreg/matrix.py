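"""Expression-matrix containers shared by all pipeline stages.

The central object is :class:`ExpressionMatrix`: a features x samples table of
non-negative abundances (raw counts or RPKM) together with a two-group sample
sheet and an optional set of control features (e.g. the endogenous control
RNU6-6P) that are displayed alongside piRNAs but excluded from co-regulation
sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "CountMatrix"]

#: Recognised unit tags.
UNITS = ("counts", "RPKM")


@dataclass
class ExpressionMatrix:
    """Features x samples abundance table with group labels.

    Parameters
    ----------
    values
        DataFrame indexed by feature id with one column per sample.
        All entries must be finite and non-negative.
    unit
        Either ``"counts"`` or ``"RPKM"``.
    groups
        Series mapping every sample id to its group label (typically
        ``"A"`` for the RA-like and ``"B"`` for the OA-like group).
        May be ``None`` for matrices that have not been annotated yet.
    controls
        Feature ids of endogenous controls; must be a subset of the
        feature index.
    """

    values: pd.DataFrame
    unit: str
    groups: pd.Series | None = None
    controls: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"unit must be one of {UNITS}, got {self.unit!r}")
        vals = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("expression values must be finite (missing values are rejected, not imputed)")
        if (vals < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        self.controls = frozenset(self.controls)
        missing_ctrl = self.controls - set(self.values.index)
        if missing_ctrl:
            raise ValueError(f"control features absent from matrix: {sorted(missing_ctrl)}")
        if self.groups is not None:
            self.groups = pd.Series(self.groups)
            missing = set(self.values.columns) - set(self.groups.index)
            if missing:
                raise ValueError(f"samples without a group label: {sorted(missing)}")
            self.groups = self.groups.loc[list(self.values.columns)]

    # -- convenience -------------------------------------------------------

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def group_labels(self) -> list:
        """Distinct group labels in first-appearance order."""
        if self.groups is None:
            raise ValueError("matrix has no sample sheet")
        return list(dict.fromkeys(self.groups))

    def samples_of(self, group) -> list:
        if self.groups is None:
            raise ValueError("matrix has no sample sheet")
        return [s for s in self.samples if self.groups[s] == group]

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        keep = [f for f in self.features if f in set(feature_ids)]
        return replace(
            self,
            values=self.values.loc[keep],
            controls=self.controls & set(keep),
        )

    def with_groups(self, groups: pd.Series) -> "ExpressionMatrix":
        return replace(self, groups=groups)


@dataclass
class CountMatrix:
    """Read-assignment result: integer counts plus per-sample accounting.

    Ambiguous reads (reference sequences shared by several ids) are
    resolved to one feature, so ``counts`` includes them; per sample,
    unambiguously assigned + ambiguous + unassigned = total reads, i.e.
    ``counts.sum() + unassigned == total``.
    """

    counts: pd.DataFrame
    unassigned: pd.Series
    ambiguous: pd.Series

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def assigned_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def to_expression(self, groups: pd.Series | None = None,
                      controls=frozenset()) -> ExpressionMatrix:
        return ExpressionMatrix(self.counts.astype(float), "counts",
                                groups=groups, controls=controls)
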