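"""Homology-threshold candidate and ortholog calling from tabular hit files.

Two filters operate on 12/14-column tab-separated pairwise-alignment hit
tables (the standard tabular layout plus optional qlen / %query-coverage
extension columns):

* candidate calling — a query is a putative factor iff its best hit (lowest
  e-value, bitscore then subject-id tie-breaks) covers strictly more than
  70% of the query;
* per-organism ortholog calling — the organism's lowest-e-value hit is
  accepted iff its identity or its query coverage strictly exceeds 50%.

Both thresholds are read as strict inequalities and are configurable.
Accepted per-organism calls assemble into a cross-species presence/absence
matrix whose cells pair in-silico identification with in-vivo validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

HIT_FIELDS_12 = [
    "query", "subject", "pct_identity", "aln_length", "mismatches", "gap_opens",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]
HIT_FIELDS_14 = HIT_FIELDS_12 + ["qlen", "pct_query_coverage"]

DEFAULT_COVERAGE_THRESHOLD = 70.0
DEFAULT_ORTHOLOG_THRESHOLD = 50.0


@dataclass(frozen=True)
class AlignmentHit:
    """One pairwise-alignment hit (1-based inclusive coordinates)."""

    query: str
    subject: str
    organism: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float
    qlen: int
    pct_query_coverage: float

    def __post_init__(self) -> None:
        if not 1 <= self.qstart <= self.qend <= self.qlen:
            raise ValueError(
                f"hit {self.query}->{self.subject}: need 1 <= qstart <= qend <= qlen, "
                f"got ({self.qstart}, {self.qend}, {self.qlen})"
            )
        if self.evalue < 0:
            raise ValueError(f"hit {self.query}->{self.subject}: negative e-value")


@dataclass
class CandidateCall:
    gene: str
    status: str  # "putative" | "rejected"
    supporting_hit: AlignmentHit | None


def _hit_from_row(values: Sequence[str], organism: str | None, line_no: int) -> AlignmentHit:
    if len(values) not in (12, 14):
        raise ValueError(f"line {line_no}: expected 12 or 14 tab-separated columns, "
                         f"got {len(values)}")
    names = HIT_FIELDS_14 if len(values) == 14 else HIT_FIELDS_12
    row = dict(zip(names, values))
    try:
        qstart, qend = int(row["qstart"]), int(row["qend"])
        if len(values) == 14:
            qlen = int(row["qlen"])
            coverage = float(row["pct_query_coverage"])
        else:
            # single best-HSP span convention
            qlen = qend  # unknown full length: span end is the floor
            coverage = 100.0 * (qend - qstart + 1) / qlen
        hit = AlignmentHit(
            query=row["query"],
            subject=row["subject"],
            organism=organism if organism is not None
            else row["subject"].split("|", 1)[0],
            pct_identity=float(row["pct_identity"]),
            aln_length=int(row["aln_length"]),
            mismatches=int(row["mismatches"]),
            gap_opens=int(row["gap_opens"]),
            qstart=qstart,
            qend=qend,
            sstart=int(row["sstart"]),
            send=int(row["send"]),
            evalue=float(row["evalue"]),
            bitscore=float(row["bitscore"]),
            qlen=qlen,
            pct_query_coverage=coverage,
        )
    except ValueError as exc:
        raise ValueError(f"line {line_no}: {exc}") from None
    return hit


def parse_hit_table(path: str | Path, organism: str | None = None,
                    qlen_map: Mapping[str, int] | None = None) -> list[AlignmentHit]:
    """Parse a 12- or 14-column tab-separated hit table.

    With 12 columns the query coverage is computed from the best-HSP span;
    supply ``qlen_map`` (query id -> full query length) for a correct
    denominator, otherwise the span end is used as a floor.  ``organism``
    labels every hit; when omitted it is taken from the subject-id prefix
    before the first ``|``.  Malformed rows raise with their line numbers.
    """
    path = Path(path)
    hits: list[AlignmentHit] = []
    errors: list[str] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            values = line.split("\t")
            if qlen_map and len(values) == 12 and values[0] in qlen_map:
                qlen = qlen_map[values[0]]
                qstart, qend = int(values[6]), int(values[7])
                values = values + [str(qlen), str(100.0 * (qend - qstart + 1) / qlen)]
            try:
                hits.append(_hit_from_row(values, organism, line_no))
            except ValueError as exc:
                errors.append(str(exc))
    if errors:
        raise ValueError(f"{path}: {len(errors)} malformed row(s):\n" + "\n".join(errors))
    if not hits:
        warnings.warn(f"{path}: no hits parsed", stacklevel=2)
    return hits


def _best_hit(hits: Sequence[AlignmentHit]) -> AlignmentHit:
    """Lowest e-value; ties break on higher bitscore, then subject id."""
    return min(hits, key=lambda h: (h.evalue, -h.bitscore, h.subject))


def call_candidates(
    hits: Iterable[AlignmentHit],
    coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD,
    queries: Iterable[str] | None = None,
) -> list[CandidateCall]:
    """Putative iff the query's best hit covers strictly more than the threshold.

    ``queries`` may list query ids with no hits at all; those are returned
    rejected with no supporting hit.
    """
    if not 0.0 < coverage_threshold <= 100.0:
        raise ValueError("coverage threshold must lie in (0, 100]")
    by_query: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        by_query.setdefault(h.query, []).append(h)
    all_queries = list(by_query)
    if queries is not None:
        all_queries += [q for q in queries if q not in by_query]
    calls = []
    for q in sorted(all_queries):
        if q not in by_query:
            calls.append(CandidateCall(gene=q, status="rejected", supporting_hit=None))
            continue
        best = _best_hit(by_query[q])
        putative = best.pct_query_coverage > coverage_threshold
        calls.append(CandidateCall(gene=q, status="putative" if putative else "rejected",
                                   supporting_hit=best))
    return calls


def best_ortholog(
    hits: Iterable[AlignmentHit],
    organism: str,
    identity_or_coverage_threshold: float = DEFAULT_ORTHOLOG_THRESHOLD,
) -> AlignmentHit | None:
    """The organism's lowest-e-value hit, iff identity or coverage strictly exceeds
    the threshold; otherwise None."""
    if not 0.0 < identity_or_coverage_threshold <= 100.0:
        raise ValueError("threshold must lie in (0, 100]")
    mine = [h for h in hits if h.organism == organism]
    if not mine:
        return None
    best = _best_hit(mine)
    t = identity_or_coverage_threshold
    if best.pct_identity > t or best.pct_query_coverage > t:
        return best
    return None


# ---------------------------------------------------------------------------
# comparative presence/absence matrix


@dataclass
class ComparativeMatrix:
    """Cross-species matrix of (in-silico, in-vivo) cell pairs.

    Cell values: first element "+"/"-" or a free-text homolog note; second
    element "+"/"-"/"" (empty = not assayed).
    """

    genes: list[str]
    organisms: list[str]
    cells: dict[tuple[str, str], tuple[str, str]]

    def __post_init__(self) -> None:
        for g in self.genes:
            for o in self.organisms:
                if (g, o) not in self.cells:
                    raise ValueError(f"missing cell for ({g!r}, {o!r})")
        for (g, o), (a, b) in self.cells.items():
            if b not in ("", "+", "-") and a in ("-",):
                raise ValueError(f"cell ({g!r}, {o!r}): in-vivo note without in-silico support")
            if b == "+" and a == "-":
                raise ValueError(
                    f"cell ({g!r}, {o!r}): in-vivo validation without in-silico call or note"
                )

    def to_dataframe(self) -> pd.DataFrame:
        data = {
            o: [",".join(self.cells[(g, o)]) for g in self.genes]
            for o in self.organisms
        }
        return pd.DataFrame(data, index=pd.Index(self.genes, name="gene"))

    def write(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    @classmethod
    def read(cls, path: str | Path) -> "ComparativeMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False)
        genes = [str(g) for g in df.index]
        organisms = [str(c) for c in df.columns]
        cells = {}
        for g in genes:
            for o in organisms:
                a, _, b = str(df.loc[g, o]).partition(",")
                cells[(g, o)] = (a, b)
        return cls(genes=genes, organisms=organisms, cells=cells)


def build_comparative_matrix(
    calls: Mapping[str, Mapping[str, object]],
    validations: Mapping[str, Mapping[str, str]] | None = None,
) -> ComparativeMatrix:
    """Assemble the matrix from per-gene, per-organism ortholog calls.

    ``calls[gene][organism]`` is True/False for presence, or a string homolog
    note passed through verbatim.  ``validations[gene][organism]`` is "+" or
    "-"; a flag for a pair with neither an in-silico call nor a note is an
    error.
    """
    validations = validations or {}
    genes = list(calls)
    organisms: list[str] = []
    for per_org in calls.values():
        for o in per_org:
            if o not in organisms:
                organisms.append(o)
    cells: dict[tuple[str, str], tuple[str, str]] = {}
    for g in genes:
        for o in organisms:
            call = calls[g].get(o, False)
            if isinstance(call, str):
                a = call
            else:
                a = "+" if call else "-"
            b = validations.get(g, {}).get(o, "")
            if b == "+" and a == "-":
                raise ValueError(
                    f"in-vivo validation flagged for ({g!r}, {o!r}) "
                    "but the gene was not identified in silico there"
                )
            cells[(g, o)] = (a, b)
    return ComparativeMatrix(genes=genes, organisms=organisms, cells=cells)


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identical columns among columns where both sequences are ungapped."""
    if len(seq_a) != len(seq_b):
        raise ValueError(f"aligned lengths differ: {len(seq_a)} vs {len(seq_b)}")
    gap = set("-.")
    comparable = ident = 0
    for x, y in zip(seq_a, seq_b):
        if x in gap or y in gap:
            continue
        comparable += 1
        ident += x == y
    if comparable == 0:
        raise ValueError("no comparable (both-ungapped) columns")
    return 100.0 * ident / comparable
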