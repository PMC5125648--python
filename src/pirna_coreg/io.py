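"""Table and configuration I/O.

Expression matrices travel as delimited text (tab by default) or XLSX with
feature ids in the first column and sample ids in the header row; sample
sheets are two-column tables (sample id, group). Decimal-comma exports are
accepted. Missing or non-numeric cells and duplicate feature ids are
rejected with coordinates — correlations on silently imputed data would be
misleading.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .matrix import ExpressionMatrix
from .reference import canonical_pirna_id

__all__ = [
    "read_expression_table",
    "write_expression_table",
    "read_sample_sheet",
    "write_sample_sheet",
    "load_config_file",
]


def _read_raw_table(path: Path, decimal: str) -> pd.DataFrame:
    if path.suffix.lower() in (".xlsx", ".xls"):
        raw = pd.read_excel(path, index_col=0)
        if decimal == ",":
            raw = raw.map(lambda v: float(str(v).replace(",", "."))
                          if isinstance(v, str) else v)
        return raw
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, index_col=0, decimal=decimal,
                       float_precision="round_trip")


def read_expression_table(path, unit: str = "RPKM", groups: pd.Series | None = None,
                          controls=frozenset(), decimal: str = ".",
                          canonicalize_ids: bool = False) -> ExpressionMatrix:
    """Read a features x samples table from TSV/CSV/XLSX.

    First column: feature ids; header row: sample ids. Duplicate ids,
    missing cells and non-numeric cells are rejected with coordinates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = _read_raw_table(path, decimal)
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate feature id(s) in {path.name}: {dups}")
    bad = []
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    for i, f in enumerate(raw.index):
        for j, s in enumerate(raw.columns):
            if pd.isna(numeric.iat[i, j]):
                bad.append(f"row {i + 2} ({f!r}), column {j + 2} ({s!r}): {raw.iat[i, j]!r}")
    if bad:
        raise ValueError(f"non-numeric or missing cells in {path.name}: " + "; ".join(bad[:5]))
    if canonicalize_ids:
        numeric.index = [canonical_pirna_id(f) for f in numeric.index]
        if pd.Index(numeric.index).has_duplicates:
            raise ValueError("feature ids collide after canonicalization")
    numeric.index.name = "feature"
    return ExpressionMatrix(numeric, unit, groups=groups, controls=controls)


def write_expression_table(E: ExpressionMatrix, path) -> None:
    # %.17g keeps the text round trip lossless at float64 precision
    E.values.to_csv(path, sep="\t", float_format="%.17g")


def read_sample_sheet(path) -> pd.Series:
    """Two-column table (sample id, group) -> Series sample -> group."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("sample sheet needs two columns: sample id, group")
    sample_col, group_col = df.columns[:2]
    if df[sample_col].duplicated().any():
        dups = df[sample_col][df[sample_col].duplicated()].tolist()
        raise ValueError(f"duplicate sample id(s) in sheet: {dups}")
    return pd.Series(df[group_col].to_numpy(), index=df[sample_col].astype(str))


def write_sample_sheet(groups: pd.Series, path) -> None:
    pd.DataFrame({"sample": groups.index, "group": groups.to_numpy()}).to_csv(
        path, sep="\t", index=False)


def load_config_file(path) -> dict:
    """Load a YAML or TOML configuration mapping."""
    path = Path(path)
    if path.suffix.lower() == ".toml":
        import tomllib
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    else:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config {path.name} must be a mapping")
    return data
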