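"""Comparative-Ct (2^-ddCT) quantification of siRNA knockdown.

Relative expression of a target gene in knocked-down cells versus the
untreated reporter line (the calibrator), normalized to an endogenous
reference transcript:

    dCT      = mean(target Ct) - mean(reference Ct)      per role
    ddCT     = dCT_sample - dCT_calibrator
    fold     = 2 ** -ddCT
    knockdown% = 100 * (1 - fold)

Amplification efficiency is fixed at 2 (the classic method, no efficiency
correction); technical replicates are averaged on the Ct scale before
differencing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

QPCR_COLUMNS = ["sample", "gene", "target_ct", "reference_ct", "well_role"]


@dataclass
class RelativeExpression:
    """2^-ddCT result for one gene (optionally one siRNA)."""

    gene: str
    delta_ct_sample: float
    delta_ct_calibrator: float
    delta_delta_ct: float
    fold_change: float
    knockdown_pct: float
    n_sample_wells: int
    n_calibrator_wells: int
    sirna: str | None = None

    @property
    def upregulated(self) -> bool:
        return self.fold_change > 1.0


def _validate_wells(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(QPCR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"qPCR table lacks columns {sorted(missing)}")
    for col in ("target_ct", "reference_ct"):
        ct = df[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(ct)) or np.any(ct <= 0) or np.any(ct >= 45):
            raise ValueError(f"{col}: Ct values must be finite and in (0, 45)")
    return df


def delta_delta_ct(wells: pd.DataFrame, gene: str, sirna: str | None = None) -> RelativeExpression:
    """Compute 2^-ddCT for one gene from a table of sample and calibrator wells."""
    df = _validate_wells(wells)
    df = df[df["gene"] == gene]
    if sirna is not None and "sirna" in df.columns:
        df = df[df["sirna"] == sirna]
    if df.empty:
        raise ValueError(f"no wells for gene {gene!r}")
    parts = {}
    for role in ("sample", "calibrator"):
        sub = df[df["well_role"] == role]
        if sub.empty:
            raise ValueError(f"gene {gene!r}: no {role} wells")
        parts[role] = (
            float(sub["target_ct"].mean()) - float(sub["reference_ct"].mean()),
            len(sub),
        )
    dct_s, n_s = parts["sample"]
    dct_c, n_c = parts["calibrator"]
    ddct = dct_s - dct_c
    fold = float(2.0 ** -ddct)
    return RelativeExpression(
        gene=gene,
        delta_ct_sample=dct_s,
        delta_ct_calibrator=dct_c,
        delta_delta_ct=ddct,
        fold_change=fold,
        knockdown_pct=100.0 * (1.0 - fold),
        n_sample_wells=n_s,
        n_calibrator_wells=n_c,
        sirna=sirna,
    )


def quantify_all(wells: pd.DataFrame) -> list[RelativeExpression]:
    """One :func:`delta_delta_ct` result per gene (x siRNA when the column exists)."""
    df = _validate_wells(wells)
    out = []
    if "sirna" in df.columns and df["sirna"].notna().any():
        keys = df[["gene", "sirna"]].drop_duplicates().itertuples(index=False)
        for gene, sirna in keys:
            out.append(delta_delta_ct(df, gene, sirna))
    else:
        for gene in df["gene"].drop_duplicates():
            out.append(delta_delta_ct(df, gene))
    return out


def knockdown_report(expressions: Iterable[RelativeExpression]) -> pd.DataFrame:
    """One row per gene (x siRNA) with fold change, knockdown % and well counts."""
    rows = [
        {
            "gene": e.gene,
            "sirna": e.sirna if e.sirna is not None else "",
            "delta_delta_ct": e.delta_delta_ct,
            "fold_change": e.fold_change,
            "knockdown_pct": e.knockdown_pct,
            "upregulated": e.upregulated,
            "n_sample_wells": e.n_sample_wells,
            "n_calibrator_wells": e.n_calibrator_wells,
        }
        for e in expressions
    ]
    return pd.DataFrame(rows, columns=["gene", "sirna", "delta_delta_ct", "fold_change",
                                       "knockdown_pct", "upregulated",
                                       "n_sample_wells", "n_calibrator_wells"])


def read_qpcr_table(path) -> pd.DataFrame:
    return _validate_wells(pd.read_csv(path, sep="\t"))


def write_qpcr_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
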