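"""The %gfp-reversion statistic and gene-level hit calling.

A test siRNA that knocks down a functional RNAi-pathway gene prevents the
co-transfected gfp siRNA from silencing the reporter, so gfp fluorescence
"reverts".  With A = % gfp-positive in the test co-transfection, B = the same
in the gfp-silenced control and C = in the untouched reporter line,

    %reversion = 100 * (A - B) / (C - B)

0 means no effect on the silencing machinery and 100 a complete rescue.
Per gene, each siRNA's replicates are averaged, the siRNA with the maximum
mean reversion is selected, and the gene is reported as that siRNA's
replicate mean +/- sample SD.  Hits are genes whose mean reversion clears a
threshold, plus an explicit forced-include list for literature-rescued genes
whose assay was uninformative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .gating import GateResult

#: report category headings, in display order; the first entry is the core
#: machinery, the rest are the auxiliary modules.
CATEGORY_ORDER = (
    "Core RNAi factors",
    "DEAD RNA helicase domain proteins",
    "RNA processing module",
    "Protein Kinase family of signalling allied components",
    "Multi drug resistance cassette transporter",
    "Tudor domain protein",
    "Sid like protein",
    "Chromatin factors",
    "Translational unit",
    "Cell division associated elements",
    "Metabolic factor",
    "Others",
)

#: default hit threshold (percent mean reversion).  Chosen to fall clearly
#: below the smallest reversion treated as real in reporter screens of this
#: design while excluding negligible responses; configurable everywhere.
DEFAULT_HIT_THRESHOLD = 5.0

#: |C - B| below this floor (percentage points) means gfp silencing failed
#: and the reversion ratio is uninformative.
DENOMINATOR_FLOOR = 0.5


class UninformativeAssayError(ValueError):
    """Raised when the silenced and reporter controls are indistinguishable."""


def reversion_pct(A: float, B: float, C: float, eps: float = DENOMINATOR_FLOOR) -> float:
    """Percent gfp reversion, 100*(A-B)/(C-B).

    Values outside [0, 100] are returned unclamped; callers flag them.
    Raises :class:`UninformativeAssayError` when |C-B| < ``eps``.
    """
    for name, v in (("A", A), ("B", B), ("C", C)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} must be a percentage in [0, 100], got {v}")
    if abs(C - B) < eps:
        raise UninformativeAssayError(
            f"|C - B| = {abs(C - B):.3g} < {eps}: gfp silencing failed, reversion undefined"
        )
    return 100.0 * (A - B) / (C - B)


@dataclass
class SirnaMeasurement:
    """One replicate's (A, B, C) triple and its derived %reversion."""

    gene: str
    sirna: str
    replicate: int
    A: float
    B: float
    C: float
    reversion: float = field(init=False)
    out_of_range: bool = field(init=False)

    def __post_init__(self) -> None:
        self.reversion = reversion_pct(self.A, self.B, self.C)
        self.out_of_range = not 0.0 <= self.reversion <= 100.0


@dataclass
class GeneSummary:
    """Per-gene aggregation over siRNAs and replicates."""

    gene: str
    per_sirna_mean: dict[str, float]
    best_sirna: str | None
    replicate_values: list[float]
    mean_reversion: float | None
    sd_reversion: float | None
    under_replicated: bool = False
    hit: bool = False
    forced_include: bool = False
    category: str | None = None


def measurements_from_gates(gates: Sequence[GateResult]) -> list[SirnaMeasurement]:
    """Join gated percentages into (A, B, C) triples.

    B and C come from the silenced/reporter control of the same replicate as
    each test sample.
    """
    controls: dict[tuple[str, int], float] = {}
    for g in gates:
        if g.role in ("silenced", "reporter"):
            controls[(g.role, g.replicate)] = g.pct_positive
    out = []
    for g in gates:
        if g.role != "test":
            continue
        try:
            b = controls[("silenced", g.replicate)]
            c = controls[("reporter", g.replicate)]
        except KeyError as exc:
            raise ValueError(
                f"test sample {g.sample_id!r}: missing {exc.args[0][0]} control "
                f"for replicate {g.replicate}"
            ) from None
        out.append(SirnaMeasurement(gene=g.gene, sirna=g.sirna, replicate=g.replicate,
                                    A=g.pct_positive, B=b, C=c))
    return out


def summarize_gene(measurements: Iterable[SirnaMeasurement], gene: str) -> GeneSummary:
    """Mean per siRNA, pick the maximum-reversion siRNA, report its mean +/- sample SD.

    Ties on the per-siRNA mean break toward the lexicographically smallest
    siRNA id.  A single replicate yields SD 0 and an under-replicated flag.
    """
    mine = [m for m in measurements if m.gene == gene]
    if not mine:
        raise ValueError(f"no measurements for gene {gene!r}")
    per_sirna: dict[str, list[float]] = {}
    for m in mine:
        per_sirna.setdefault(m.sirna, []).append(m.reversion)
    means = {s: float(np.mean(v)) for s, v in sorted(per_sirna.items())}
    top = max(means.values())
    best = min(s for s in means if means[s] == top)  # ties -> smallest siRNA id
    reps = per_sirna[best]
    sd = float(np.std(reps, ddof=1)) if len(reps) > 1 else 0.0
    return GeneSummary(
        gene=gene,
        per_sirna_mean=means,
        best_sirna=best,
        replicate_values=list(reps),
        mean_reversion=means[best],
        sd_reversion=sd,
        under_replicated=len(reps) < 2,
    )


def summarize_screen(measurements: Sequence[SirnaMeasurement]) -> list[GeneSummary]:
    genes = sorted({m.gene for m in measurements})
    return [summarize_gene(measurements, g) for g in genes]


def call_hits(
    summaries: Iterable[GeneSummary],
    threshold: float = DEFAULT_HIT_THRESHOLD,
    forced: Iterable[str] = (),
    categories: Mapping[str, str] | None = None,
) -> list[GeneSummary]:
    """Flag hits (mean reversion >= threshold, or forced) and order by category, gene.

    ``forced`` lists genes included on external evidence even when the assay
    did not score them; these carry ``forced_include=True``.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    forced = set(forced)
    out = []
    for s in summaries:
        by_value = s.mean_reversion is not None and s.mean_reversion >= threshold
        s.hit = by_value or s.gene in forced
        s.forced_include = s.gene in forced and not by_value
        if categories is not None:
            cat = categories.get(s.gene)
            if cat is not None and cat not in CATEGORY_ORDER:
                raise ValueError(f"unknown category label {cat!r} for gene {s.gene!r}")
            s.category = cat
        out.append(s)

    def key(s: GeneSummary) -> tuple[int, str]:
        rank = CATEGORY_ORDER.index(s.category) if s.category in CATEGORY_ORDER \
            else len(CATEGORY_ORDER)
        return rank, s.gene

    return sorted(out, key=key)


def screen_report(
    hits: Iterable[GeneSummary],
    identities: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Tabular report: category, gene, %reversion (+/- SD), per-organism identity columns.

    ``identities`` is indexed by gene with one column per organism; missing
    genes leave the identity cells empty.
    """
    rows = []
    for s in hits:
        if not s.hit:
            continue
        rows.append(
            {
                "category": s.category or "",
                "gene": s.gene,
                "pct_reversion": s.mean_reversion if not s.forced_include else np.nan,
                "sd_reversion": s.sd_reversion if not s.forced_include else np.nan,
                "forced_include": s.forced_include,
            }
        )
    report = pd.DataFrame(rows, columns=["category", "gene", "pct_reversion",
                                         "sd_reversion", "forced_include"])
    if identities is not None and not report.empty:
        report = report.merge(identities, how="left", left_on="gene", right_index=True)
    elif identities is not None:
        for col in identities.columns:
            report[col] = pd.Series(dtype=float)
    return report


def sirna_long_table(measurements: Sequence[SirnaMeasurement]) -> pd.DataFrame:
    """Per-siRNA long-format table (sample, siRNA set, %gfp triple, reversion)."""
    return pd.DataFrame(
        {
            "gene": [m.gene for m in measurements],
            "sirna": [m.sirna for m in measurements],
            "replicate": [m.replicate for m in measurements],
            "pct_gfp_test": [m.A for m in measurements],
            "pct_gfp_silenced": [m.B for m in measurements],
            "pct_gfp_reporter": [m.C for m in measurements],
            "pct_reversion": [m.reversion for m in measurements],
            "out_of_range": [m.out_of_range for m in measurements],
        }
    )
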