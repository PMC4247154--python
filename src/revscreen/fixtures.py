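"""Bundled reference fixtures.

Transcriptions of the published screen summary (42 validated factors with
category, %gfp reversion and per-organism identity columns), the
cross-species comparative presence/absence matrix, and the two control
siRNA sequences.  A handful of identity integers and trailing matrix cells
were ambiguous in the source text and are best-effort; the reversion
percentages and hit accounting are exact.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .orthologs import ComparativeMatrix
from .reversion import GeneSummary

#: gene rescued into the validated set on literature evidence despite an
#: uninformative reversion assay.
FORCED_INCLUDE_GENES = frozenset({"Tudor"})


def _data_path(name: str):
    return resources.files("revscreen.data").joinpath(name)


def load_screen_table() -> pd.DataFrame:
    """The 42-gene validated-factor table: category, gene, %reversion, identities."""
    with resources.as_file(_data_path("table1_screen.tsv")) as p:
        df = pd.read_csv(p, sep="\t", keep_default_na=False)
    df["pct_reversion"] = pd.to_numeric(df["pct_reversion"], errors="coerce")
    for col in ("identity_bm", "identity_tc", "identity_dm"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["forced_include"] = df["forced_include"].astype(str).str.lower() == "true"
    return df


def load_comparative_matrix() -> ComparativeMatrix:
    """The cross-species (in-silico, in-vivo) presence/absence matrix."""
    with resources.as_file(_data_path("table2_matrix.tsv")) as p:
        return ComparativeMatrix.read(p)


def load_control_sirnas() -> pd.DataFrame:
    """The gfp-silencing and scrambled control siRNA sequences."""
    with resources.as_file(_data_path("control_sirnas.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def screen_table_summaries(df: pd.DataFrame | None = None) -> list[GeneSummary]:
    """Re-express the fixture table as :class:`GeneSummary` records for hit calling.

    Each row carries only the reported best-siRNA mean (replicate values were
    not published), so SD is unavailable and the summaries are marked
    under-replicated.
    """
    if df is None:
        df = load_screen_table()
    out = []
    for row in df.itertuples(index=False):
        mean = None if pd.isna(row.pct_reversion) else float(row.pct_reversion)
        out.append(
            GeneSummary(
                gene=row.gene,
                per_sirna_mean={} if mean is None else {"reported": mean},
                best_sirna=None if mean is None else "reported",
                replicate_values=[] if mean is None else [mean],
                mean_reversion=mean,
                sd_reversion=None,
                under_replicated=True,
                category=row.category,
            )
        )
    return out


def screen_table_identities(df: pd.DataFrame | None = None) -> pd.DataFrame:
    if df is None:
        df = load_screen_table()
    return df.set_index("gene")[["identity_bm", "identity_tc", "identity_dm"]]


def screen_table_categories(df: pd.DataFrame | None = None) -> dict[str, str]:
    if df is None:
        df = load_screen_table()
    return dict(zip(df["gene"], df["category"]))
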