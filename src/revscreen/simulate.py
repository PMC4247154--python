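"""Synthetic data generators for every pipeline stage.

Three generators, each driven by an explicit statistical model and a seed:

* flow-cytometry event tables — a two-component log-location (log-normal)
  mixture of gfp-negative and gfp-positive events, with the positive fraction
  set by the population role (plain parental line, unsilenced reporter,
  gfp-siRNA-silenced reporter, test co-transfection);
* qPCR Ct tables with a known fold-change structure against an endogenous
  reference and a calibrator line;
* toy protein families evolved on a known tree, together with their
  all-vs-all tabular hit records.

Reproducibility: one shared seed is split into independent per-sample
substreams keyed by a deterministic sample counter, so a sample's events do
not depend on the order in which samples are drawn.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .gating import EventTable
from .phylo import DELETION_CHARS, MultipleAlignment

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

HIT_COLUMNS = [
    "query", "subject", "pct_identity", "aln_length", "mismatches", "gap_opens",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore", "qlen", "pct_query_coverage",
]


def _substream(seed: int, key: int) -> np.random.Generator:
    """Independent generator for substream ``key`` of the run seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


# ---------------------------------------------------------------------------
# flow-cytometry screen


class ScreenSimConfig(BaseModel):
    """Design and effect structure of one simulated reversion screen.

    ``effect_map`` holds each gene's true reversion effect r in [0, 1]:
    the fraction of silencing-suppressed gfp-positive cells restored when the
    gene is knocked down (0 = no role in RNAi, 1 = complete rescue).
    ``sirna_efficacy`` multiplies r per siRNA so that max-over-siRNA
    aggregation is exercised; the default spread reflects the routinely
    heterogeneous potency of independently designed siRNAs against one gene.
    """

    model_config = {"extra": "forbid"}

    effect_map: dict[str, float]
    sirnas_per_gene: int = 3
    n_replicates: int = 3
    events_per_sample: int = 10_000
    mu_neg: float = math.log(10.0)
    sigma_neg: float = 0.5
    mu_pos: float = math.log(1000.0)
    sigma_pos: float = 0.5
    pi_reporter: float = Field(0.9, ge=0.0, le=1.0)
    silencing_efficiency: float = Field(0.9, ge=0.0, le=1.0)
    sirna_efficacy: tuple[float, ...] = (1.0, 0.6, 0.3)
    seed: int = 0

    @field_validator("effect_map")
    @classmethod
    def _effects_in_unit_interval(cls, v: dict[str, float]) -> dict[str, float]:
        for gene, r in v.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"effect for {gene!r} must lie in [0, 1], got {r}")
        return v

    @model_validator(mode="after")
    def _check_model(self) -> "ScreenSimConfig":
        if self.mu_pos <= self.mu_neg:
            raise ValueError("mu_pos must exceed mu_neg (positive population is brighter)")
        if any(not 0.0 <= e <= 1.0 for e in self.sirna_efficacy):
            raise ValueError("sirna_efficacy multipliers must lie in [0, 1]")
        if self.sirnas_per_gene < 1 or self.n_replicates < 1 or self.events_per_sample < 1:
            raise ValueError("counts must be >= 1")
        return self

    @property
    def n_genes(self) -> int:
        return len(self.effect_map)

    @property
    def genes(self) -> list[str]:
        return list(self.effect_map)

    def sirna_ids(self) -> list[str]:
        return [f"s{i + 1}" for i in range(self.sirnas_per_gene)]

    def efficacy(self, sirna_index: int) -> float:
        # pad a short multiplier list by repeating its last entry
        eff = self.sirna_efficacy
        return eff[min(sirna_index, len(eff) - 1)]


def positive_fraction(config: ScreenSimConfig, role: str, gene: str | None = None,
                      sirna: str | None = None) -> float:
    """Closed-form gfp-positive mixture fraction for a population role.

    plain: 0; reporter: pi; silenced: pi*(1 - s); test: pi_B + r_eff*(pi - pi_B)
    with r_eff = r * per-siRNA efficacy.
    """
    pi = config.pi_reporter
    pi_b = pi * (1.0 - config.silencing_efficiency)
    if role == "plain":
        return 0.0
    if role == "reporter":
        return pi
    if role == "silenced":
        return pi_b
    if role == "test":
        if gene is None or sirna is None:
            raise ValueError("test samples need gene and sirna labels")
        if gene not in config.effect_map:
            raise KeyError(f"no reversion effect configured for gene {gene!r}")
        sirna_ids = config.sirna_ids()
        if sirna not in sirna_ids:
            raise KeyError(f"unknown siRNA id {sirna!r}; expected one of {sirna_ids}")
        r_eff = config.effect_map[gene] * config.efficacy(sirna_ids.index(sirna))
        return pi_b + r_eff * (pi - pi_b)
    raise ValueError(f"unknown population role {role!r}")


def _sample_key(config: ScreenSimConfig, role: str, gene: str | None,
                sirna: str | None, replicate: int) -> int:
    """Deterministic substream counter: controls first, then test wells in design order."""
    control_roles = ("plain", "reporter", "silenced")
    if role in control_roles:
        return control_roles.index(role) * config.n_replicates + replicate
    base = 3 * config.n_replicates
    g = config.genes.index(gene)
    s = config.sirna_ids().index(sirna)
    return base + (g * config.sirnas_per_gene + s) * config.n_replicates + replicate


def simulate_facs_sample(config: ScreenSimConfig, role: str, gene: str | None = None,
                         sirna: str | None = None, replicate: int = 0) -> EventTable:
    """Draw one well's events from the two-component log-normal mixture."""
    if role != "test" and (gene is not None or sirna is not None):
        raise ValueError("gene/sirna labels are only valid for test samples")
    pi = positive_fraction(config, role, gene, sirna)
    rng = _substream(config.seed, _sample_key(config, role, gene, sirna, replicate))
    n = config.events_per_sample
    is_pos = rng.random(n) < pi
    z = rng.standard_normal(n)
    log_fl = np.where(is_pos, config.mu_pos + config.sigma_pos * z,
                      config.mu_neg + config.sigma_neg * z)
    if role == "test":
        sample_id = f"{gene}_{sirna}_r{replicate + 1}"
    else:
        sample_id = f"{role}_r{replicate + 1}"
    return EventTable(sample_id=sample_id, role=role, gene=gene, sirna=sirna,
                      replicate=replicate, events=np.exp(log_fl))


def simulate_screen(config: ScreenSimConfig) -> list[EventTable]:
    """One full plate: 3 control roles x replicates, plus every gene x siRNA x replicate."""
    samples: list[EventTable] = []
    for role in ("plain", "reporter", "silenced"):
        for rep in range(config.n_replicates):
            samples.append(simulate_facs_sample(config, role, replicate=rep))
    for gene in config.genes:
        for sirna in config.sirna_ids():
            for rep in range(config.n_replicates):
                samples.append(simulate_facs_sample(config, "test", gene, sirna, rep))
    return samples


# ---------------------------------------------------------------------------
# qPCR


class QpcrSimConfig(BaseModel):
    """Comparative-Ct experiment with a known remaining-expression fraction per gene.

    For a knocked-down gene with remaining expression f (``true_fold_change``),
    sample-well target Cts sit ``-log2(f)`` cycles above the calibrator line's
    target Cts, with Gaussian cycle noise of sd ``ct_noise_sd`` added per
    well; reference-channel (endogenous control) Cts share the one fixed
    mean ``ct_reference_mean`` in every well.
    """

    model_config = {"extra": "forbid"}

    genes: list[str]
    true_fold_change: dict[str, float]
    ct_reference_mean: float = 16.0
    ct_target_calibrator_mean: float = 24.0
    ct_noise_sd: float = Field(0.2, ge=0.0)
    n_bio_replicates: int = 2
    n_tech_replicates: int = 3
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "QpcrSimConfig":
        for g in self.genes:
            f = self.true_fold_change.get(g)
            if f is None:
                raise ValueError(f"no true fold change configured for gene {g!r}")
            if f <= 0:
                raise ValueError(f"fold change for {g!r} must be positive, got {f}")
        if self.n_bio_replicates < 1 or self.n_tech_replicates < 1:
            raise ValueError("replicate counts must be >= 1")
        return self


def simulate_qpcr(config: QpcrSimConfig) -> pd.DataFrame:
    """Emit one Ct table row per well: sample and calibrator wells for every gene."""
    rows = []
    for gi, gene in enumerate(config.genes):
        rng = _substream(config.seed, gi)
        shift = -math.log2(config.true_fold_change[gene])
        for well_role, target_mean in (
            ("calibrator", config.ct_target_calibrator_mean),
            ("sample", config.ct_target_calibrator_mean + shift),
        ):
            for bio in range(config.n_bio_replicates):
                for tech in range(config.n_tech_replicates):
                    noise = float(rng.normal(0.0, config.ct_noise_sd)) \
                        if config.ct_noise_sd > 0 else 0.0
                    rows.append(
                        {
                            "sample": f"{gene}_{well_role}_b{bio + 1}t{tech + 1}",
                            "gene": gene,
                            "target_ct": target_mean + noise,
                            "reference_ct": config.ct_reference_mean,
                            "well_role": well_role,
                            "bio_replicate": bio,
                            "tech_replicate": tech,
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# protein families on a known tree


class SeqSimConfig(BaseModel):
    """Protein family evolved along a fixed tree by per-branch i.i.d. substitution.

    ``tree`` is an edge list ``(parent, child, p)``: with probability p each
    site is redrawn uniformly from the alphabet on that branch (the redraw may
    restore the original residue).  For two leaves joined by branches p1, p2
    the expected per-site mismatch is (1 - (1-p1)(1-p2)) * (k-1)/k for a
    k-letter alphabet.  ``gap_rate`` punches a gap into one uniformly chosen
    taxon per column.  No indels are modelled beyond these gap columns.
    """

    model_config = {"extra": "forbid"}

    tree: list[tuple[str, str, float]]
    seq_length: int = 200
    alphabet: str = AMINO_ACIDS
    gap_rate: float = Field(0.0, ge=0.0, lt=1.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SeqSimConfig":
        if self.seq_length < 1:
            raise ValueError("seq_length must be >= 1")
        if len(set(self.alphabet)) < 2:
            raise ValueError("alphabet needs at least two symbols")
        if set(self.alphabet) & DELETION_CHARS:
            raise ValueError("alphabet must not contain gap/missing symbols")
        children = [c for _, c, _ in self.tree]
        if len(set(children)) != len(children):
            raise ValueError("tree edge list assigns a node two parents")
        for p, c, prob in self.tree:
            if not 0.0 <= prob < 1.0:
                raise ValueError(f"branch {p}->{c}: substitution probability must be in [0, 1)")
        self.root()  # raises on a disconnected forest
        return self

    def root(self) -> str:
        parents = {p for p, _, _ in self.tree}
        children = {c for _, c, _ in self.tree}
        roots = parents - children
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {sorted(roots)}")
        # every node must be reachable from the root
        adj: dict[str, list[str]] = {}
        for p, c, _ in self.tree:
            adj.setdefault(p, []).append(c)
        seen, stack = set(), [next(iter(roots))]
        while stack:
            node = stack.pop()
            seen.add(node)
            stack.extend(adj.get(node, []))
        if seen != parents | children:
            raise ValueError("tree is disconnected")
        return next(iter(roots))

    def leaves(self) -> list[str]:
        parents = {p for p, _, _ in self.tree}
        return sorted(c for _, c, _ in self.tree if c not in parents)

    @property
    def n_taxa(self) -> int:
        return len(self.leaves())


def expected_leaf_identity(config: SeqSimConfig, taxon_a: str, taxon_b: str) -> float:
    """Closed-form expected % identity between two leaves under the redraw model."""
    parent_of = {c: (p, prob) for p, c, prob in config.tree}

    def path_to_root(node: str) -> list[str]:
        path = [node]
        while path[-1] in parent_of:
            path.append(parent_of[path[-1]][0])
        return path

    pa, pb = path_to_root(taxon_a), path_to_root(taxon_b)
    common = set(pa) & set(pb)
    mrca = next(n for n in pa if n in common)
    survive = 1.0
    for leaf_path in (pa, pb):
        for node in leaf_path[: leaf_path.index(mrca)]:
            survive *= 1.0 - parent_of[node][1]
    k = len(config.alphabet)
    mismatch = (1.0 - survive) * (k - 1) / k
    return 100.0 * (1.0 - mismatch)


def simulate_protein_family(config: SeqSimConfig) -> tuple[MultipleAlignment, pd.DataFrame]:
    """Evolve the family and emit the aligned FASTA rows plus an all-vs-all hit table.

    Hit identities equal ``100 * (1 - observed p-distance)`` over columns
    where both sequences are ungapped, so they agree exactly with
    :func:`revscreen.orthologs.pairwise_identity` on the same rows.
    """
    rng = _substream(config.seed, 0)
    root = config.root()
    alpha = np.frombuffer(config.alphabet.encode("ascii"), dtype="S1")
    k, L = len(alpha), config.seq_length

    seqs: dict[str, np.ndarray] = {root: alpha[rng.integers(0, k, size=L)]}
    # parent sequences are always generated before children: walk edges in
    # topological order from the root
    pending = list(config.tree)
    while pending:
        progressed = False
        for edge in list(pending):
            parent, child, p = edge
            if parent in seqs:
                seq = seqs[parent].copy()
                hit = rng.random(L) < p
                seq[hit] = alpha[rng.integers(0, k, size=int(hit.sum()))]
                seqs[child] = seq
                pending.remove(edge)
                progressed = True
        if not progressed:  # unreachable after config validation
            raise ValueError("tree is disconnected")

    taxa = config.leaves()
    rows = np.stack([seqs[t] for t in taxa])
    if config.gap_rate > 0:
        gap_cols = rng.random(L) < config.gap_rate
        victims = rng.integers(0, len(taxa), size=int(gap_cols.sum()))
        rows[victims, np.flatnonzero(gap_cols)] = b"-"
    aln = MultipleAlignment(taxa=taxa, rows=[r.tobytes().decode("ascii") for r in rows])

    hits = []
    for i, qt in enumerate(taxa):
        for j, st in enumerate(taxa):
            if i == j:
                continue
            both = (rows[i] != b"-") & (rows[j] != b"-")
            comparable = int(both.sum())
            mism = int(np.count_nonzero(rows[i][both] != rows[j][both]))
            ident = 100.0 * (comparable - mism) / comparable
            bitscore = 2.0 * (comparable - mism)
            evalue = max(comparable * 2.0 ** (-bitscore), 1e-300)
            hits.append(
                {
                    "query": qt, "subject": st, "pct_identity": ident,
                    "aln_length": comparable, "mismatches": mism, "gap_opens": 0,
                    "qstart": 1, "qend": comparable, "sstart": 1, "send": comparable,
                    "evalue": evalue, "bitscore": bitscore, "qlen": comparable,
                    "pct_query_coverage": 100.0,
                }
            )
    return aln, pd.DataFrame(hits, columns=HIT_COLUMNS)
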