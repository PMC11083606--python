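"""Readers and writers for the pipeline's delimited-text artifacts.

All tables are plain delimited text (tab by default, comma auto-detected):
expression matrices with genes as rows and a header of sample IDs, drug
screens with cell lines as rows and drugs as columns (missing entries as
``NA``), two-column label files, long-format dose-response tables, and a
JSON sidecar for simulation ground truth.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .dose_response import DoseResponseCurve
from .simulate import SyntheticTruth

__all__ = [
    "read_expression", "write_expression",
    "read_screen", "write_screen",
    "read_labels", "write_labels",
    "read_truth", "write_truth",
    "read_dose_response", "write_dose_response",
    "write_table",
]

_NA = "NA"


def _detect_sep(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _read_matrix(path, kind: str, row_kind: str, col_kind: str) -> pd.DataFrame:
    path = Path(path)
    sep = _detect_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0, na_values=[_NA])
    for axis_name, ids in ((row_kind, df.index), (col_kind, df.columns)):
        dup = ids[ids.duplicated()].unique().tolist()
        if dup:
            raise ValueError(f"{path}: duplicate {axis_name} IDs: {dup[:5]}")
    bad = df.apply(lambda c: ~c.map(lambda v: isinstance(v, (int, float)) or pd.isna(v)))
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {df.iat[r, c]!r} in {kind} at "
            f"row {df.index[r]!r}, column {df.columns[c]!r}")
    df = df.astype(float)
    df.index.name = None
    df.columns.name = None
    return df


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples expression matrix (TSV or CSV)."""
    return _read_matrix(path, "expression matrix", "gene", "sample")


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene", na_rep=_NA)


def read_screen(path) -> pd.DataFrame:
    """Read a cell-lines x drugs AUC screen; ``NA`` marks unscreened pairs."""
    return _read_matrix(path, "drug screen", "cell line", "drug")


def write_screen(screen: pd.DataFrame, path) -> None:
    screen.to_csv(path, sep="\t", index_label="cell_line", na_rep=_NA)


def read_labels(path) -> pd.Series:
    """Read a two-column (sample_id, group) TSV into a sample -> group map."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns sample_id, group")
    s = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0], name="group")
    dup = s.index[s.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"{path}: duplicate sample IDs: {dup[:5]}")
    return s


def write_labels(labels: pd.Series, path) -> None:
    pd.DataFrame({"sample_id": labels.index, "group": labels.to_numpy()}).to_csv(
        path, sep="\t", index=False)


def read_truth(path) -> SyntheticTruth:
    return SyntheticTruth.from_json(Path(path).read_text())


def write_truth(truth: SyntheticTruth, path) -> None:
    Path(path).write_text(truth.to_json())


def write_dose_response(curves: list[DoseResponseCurve], path) -> None:
    """Write curves as long-format TSV: sample, drug, dose_nM, replicate, atp."""
    rows = []
    for c in curves:
        for rep in range(c.atp.shape[0]):
            for j, dose in enumerate(c.doses):
                rows.append((c.sample_id, c.drug_id, dose, rep, c.atp[rep, j]))
    pd.DataFrame(rows, columns=["sample_id", "drug", "dose_nM", "replicate",
                                "relative_atp"]).to_csv(path, sep="\t", index=False)


def read_dose_response(path) -> list[DoseResponseCurve]:
    """Read a long-format dose-response TSV back into per-sample curves."""
    df = pd.read_csv(path, sep="\t")
    needed = {"sample_id", "drug", "dose_nM", "replicate", "relative_atp"}
    if not needed.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(needed - set(df.columns))}")
    curves = []
    for (sample, drug), grp in df.groupby(["sample_id", "drug"], sort=True):
        wide = grp.pivot_table(index="replicate", columns="dose_nM",
                               values="relative_atp").sort_index(axis=1)
        curves.append(DoseResponseCurve(
            doses=wide.columns.to_numpy(dtype=float),
            atp=wide.to_numpy(dtype=float),
            sample_id=str(sample), drug_id=str(drug)))
    return curves


def write_table(df: pd.DataFrame, path) -> None:
    """Write a tidy result table as TSV (no index)."""
    df.to_csv(path, sep="\t", index=False, na_rep=_NA)
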