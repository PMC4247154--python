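"""Threshold gating of event-level fluorescence.

Converts per-event FL1 fluorescence into the percent-gfp-positive quantity
("% of the parent gate") that the reversion statistic consumes.  The gate is
a single-channel threshold derived from a non-fluorescent control line; the
parent gate is all events (no scatter gating is modelled).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: population roles: plain parental line, unsilenced gfp reporter line,
#: gfp-siRNA-silenced reporter, and the test co-transfection.
ROLES = ("plain", "reporter", "silenced", "test")

EVENT_COLUMNS = ["sample_id", "role", "gene", "sirna", "replicate", "fl1"]


@dataclass
class EventTable:
    """Per-event fluorescence values for one well/sample.

    Parameters
    ----------
    sample_id : str
        Unique label for the well.
    role : str
        One of :data:`ROLES`.
    gene, sirna : str or None
        Test-sample annotations; ``None`` for control roles.
    replicate : int
        Independent-transfection index (0-based).
    events : numpy.ndarray
        Linear-scale fluorescence, one value per event; finite and >= 0.
    """

    sample_id: str
    role: str
    gene: str | None
    sirna: str | None
    replicate: int
    events: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown population role {self.role!r}; expected one of {ROLES}")
        self.events = np.asarray(self.events, dtype=float)
        if self.events.ndim != 1 or self.events.size < 1:
            raise ValueError(f"sample {self.sample_id!r}: need a 1-D array with at least one event")
        if not np.all(np.isfinite(self.events)) or np.any(self.events < 0):
            raise ValueError(f"sample {self.sample_id!r}: fluorescence must be finite and >= 0")

    @property
    def n_events(self) -> int:
        return int(self.events.size)


@dataclass
class GateResult:
    """Gate summary for one sample: events above threshold, as a count and percent."""

    sample_id: str
    threshold: float
    n_events: int
    n_positive: int
    role: str = "test"
    gene: str | None = None
    sirna: str | None = None
    replicate: int = 0

    @property
    def pct_positive(self) -> float:
        return 100.0 * self.n_positive / self.n_events


def derive_gate_threshold(negative_control: EventTable, quantile: float = 0.995) -> float:
    """Set the positivity threshold at an upper quantile of the plain (gfp-negative) line.

    By construction at most ``1 - quantile`` of negative-control events
    exceed the returned value.  The default 0.995 mirrors routine
    negative-control gating practice.
    """
    if negative_control.role != "plain":
        raise ValueError(
            f"gate threshold must come from the plain line, got role {negative_control.role!r}"
        )
    if not 0.0 < quantile < 1.0:
        raise ValueError(f"quantile must lie strictly inside (0, 1), got {quantile}")
    return float(np.quantile(negative_control.events, quantile))


def gate_positive_fraction(sample: EventTable, threshold: float) -> GateResult:
    """Count events strictly above ``threshold`` and report the percent positive."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    n_pos = int(np.count_nonzero(sample.events > threshold))
    return GateResult(
        sample_id=sample.sample_id,
        threshold=float(threshold),
        n_events=sample.n_events,
        n_positive=n_pos,
        role=sample.role,
        gene=sample.gene,
        sirna=sample.sirna,
        replicate=sample.replicate,
    )


def gate_samples(
    samples: Iterable[EventTable],
    threshold: float | None = None,
    quantile: float = 0.995,
) -> list[GateResult]:
    """Gate a whole plate.

    When ``threshold`` is None it is derived from the pooled plain-line
    samples at ``quantile``.
    """
    samples = list(samples)
    if threshold is None:
        plain = [s for s in samples if s.role == "plain"]
        if not plain:
            raise ValueError("no plain-line sample to derive the gate threshold from")
        pooled = EventTable(
            sample_id="__pooled_plain__",
            role="plain",
            gene=None,
            sirna=None,
            replicate=0,
            events=np.concatenate([s.events for s in plain]),
        )
        threshold = derive_gate_threshold(pooled, quantile=quantile)
    return [gate_positive_fraction(s, threshold) for s in samples]


# ---------------------------------------------------------------------------
# delimited IO


def write_event_tables(samples: Sequence[EventTable], path: str | Path) -> None:
    """Write samples as long-format delimited text (one row per event)."""
    frames = []
    for s in samples:
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": s.sample_id,
                    "role": s.role,
                    "gene": s.gene if s.gene is not None else "",
                    "sirna": s.sirna if s.sirna is not None else "",
                    "replicate": s.replicate,
                    "fl1": s.events,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_event_tables(path: str | Path) -> list[EventTable]:
    """Read the long-format event table written by :func:`write_event_tables`."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "sirna": str}, keep_default_na=False)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event table {path} lacks columns {sorted(missing)}")
    out = []
    for sid, grp in df.groupby("sample_id", sort=False):
        first = grp.iloc[0]
        out.append(
            EventTable(
                sample_id=str(sid),
                role=str(first["role"]),
                gene=str(first["gene"]) or None,
                sirna=str(first["sirna"]) or None,
                replicate=int(first["replicate"]),
                events=grp["fl1"].to_numpy(dtype=float),
            )
        )
    return out


def gate_results_to_frame(gates: Sequence[GateResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [g.sample_id for g in gates],
            "role": [g.role for g in gates],
            "gene": [g.gene if g.gene is not None else "" for g in gates],
            "sirna": [g.sirna if g.sirna is not None else "" for g in gates],
            "replicate": [g.replicate for g in gates],
            "threshold": [g.threshold for g in gates],
            "n_events": [g.n_events for g in gates],
            "n_positive": [g.n_positive for g in gates],
            "pct_positive": [g.pct_positive for g in gates],
        }
    )


def gate_results_from_frame(df: pd.DataFrame) -> list[GateResult]:
    out = []
    for row in df.itertuples(index=False):
        gene = getattr(row, "gene", "")
        sirna = getattr(row, "sirna", "")
        out.append(
            GateResult(
                sample_id=str(row.sample_id),
                threshold=float(row.threshold),
                n_events=int(row.n_events),
                n_positive=int(row.n_positive),
                role=str(row.role),
                gene=str(gene) if str(gene) not in ("", "nan") else None,
                sirna=str(sirna) if str(sirna) not in ("", "nan") else None,
                replicate=int(row.replicate),
            )
        )
    return out
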