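"""Distance-based phylogenetics on aligned amino-acid sequences.

The procedure: complete deletion of gap/missing columns, p-distance
(amino-acid differences per retained site), Saitou-Nei neighbour joining on
the Q-criterion, and nonparametric bootstrap support from column resampling.
Trees are :class:`skbio.TreeNode` objects; supports live on
``node.support`` of internal nodes and are serialized as integer internal
node labels in Newick.

Numerical conventions, chosen for cross-platform determinism:

* Q-matrix ties break on the smallest (i, j) index pair in the current
  join order;
* a negative estimated branch length is set to zero and the deficit moved
  onto its sibling edge (the final 3-way star simply clamps at zero);
* bootstrap resampling draws columns with a seeded PCG64 generator, so a
  fixed seed reproduces supports bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from skbio import TreeNode

#: columns containing any of these symbols in any row are removed by
#: complete deletion (gap, missing datum, unresolved residue).
DELETION_CHARS = frozenset("-.?X")


@dataclass
class MultipleAlignment:
    """An aligned set of amino-acid sequences (equal-length gapped rows)."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("one row per taxon required")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxon labels must be unique")
        if not self.rows:
            raise ValueError("empty alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            bad = next(t for t, r in zip(self.taxa, self.rows) if len(r) != len(self.rows[0]))
            raise ValueError(f"ragged alignment: row {bad!r} differs in length")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def as_array(self) -> np.ndarray:
        """(n_taxa, length) array of single bytes."""
        return np.array([np.frombuffer(r.encode("ascii"), dtype="S1") for r in self.rows])


@dataclass
class DistanceMatrix:
    """Symmetric p-distance matrix plus the number of retained columns."""

    taxa: list[str]
    values: np.ndarray = field(repr=False)
    n_sites_used: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if v.shape != (n, n):
            raise ValueError(f"expected a {n}x{n} matrix, got {v.shape}")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must be symmetric with a zero diagonal")
        self.values = v

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxa, columns=self.taxa)


def complete_deletion(aln: MultipleAlignment) -> MultipleAlignment:
    """Drop every column holding a gap or missing symbol in any row."""
    arr = aln.as_array()
    bad = np.zeros(aln.length, dtype=bool)
    for ch in DELETION_CHARS:
        bad |= (arr == ch.encode("ascii")).any(axis=0)
    keep = ~bad
    if not keep.any():
        raise ValueError("complete deletion removed every column")
    kept = arr[:, keep]
    return MultipleAlignment(taxa=list(aln.taxa),
                             rows=[r.tobytes().decode("ascii") for r in kept])


def p_distance_matrix(aln: MultipleAlignment) -> DistanceMatrix:
    """Pairwise fraction of differing residues per site, after complete deletion."""
    clean = complete_deletion(aln)
    arr = clean.as_array()
    n, L = arr.shape
    d = np.zeros((n, n))
    for i in range(n):
        diff = (arr[i] != arr[i + 1:]).mean(axis=1) if i + 1 < n else []
        d[i, i + 1:] = diff
        d[i + 1:, i] = diff
    return DistanceMatrix(taxa=list(clean.taxa), values=d, n_sites_used=L)


# ---------------------------------------------------------------------------
# neighbour joining


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbour joining.

    Returns an unrooted tree presented with a trifurcating root (or, for two
    taxa, a root splitting the single edge at its midpoint).  For an additive
    input the generating topology and all path lengths are recovered exactly.
    """
    n = len(dm.taxa)
    if n < 2:
        raise ValueError("need at least two taxa")
    if n == 2:
        half = float(dm.values[0, 1]) / 2.0
        return TreeNode(children=[TreeNode(name=dm.taxa[0], length=half),
                                  TreeNode(name=dm.taxa[1], length=half)])

    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.taxa]
    d = dm.values.astype(float).copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        q[np.tril_indices(m)] = np.inf
        i, j = np.unravel_index(int(np.argmin(q)), q.shape)  # row-major argmin
        # argmin over the upper triangle is lexicographic in (i, j) already

        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        if li < 0.0:
            lj += li
            li = 0.0
        if lj < 0.0:
            li += lj
            lj = 0.0
        nodes[i].length = float(li)
        nodes[j].length = float(lj)
        parent = TreeNode(children=[nodes[i], nodes[j]])

        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep],
                       dnew[keep][None, :]])
        d = np.hstack([d, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    (x, y, z), dd = nodes, d
    lx = max(0.0, 0.5 * (dd[0, 1] + dd[0, 2] - dd[1, 2]))
    ly = max(0.0, 0.5 * (dd[0, 1] + dd[1, 2] - dd[0, 2]))
    lz = max(0.0, 0.5 * (dd[0, 2] + dd[1, 2] - dd[0, 1]))
    for node, length in zip((x, y, z), (lx, ly, lz)):
        node.length = float(length)
    return TreeNode(children=[x, y, z])


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Nontrivial unrooted splits, each canonicalized to its lexicographically smaller side."""
    taxa = frozenset(t.name for t in tree.tips())
    parts: set[frozenset[str]] = set()
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        if 2 <= len(side) <= len(taxa) - 2:
            other = taxa - side
            parts.add(min(side, other, key=lambda s: tuple(sorted(s))))
    return parts


def bootstrap_support(aln: MultipleAlignment, n_reps: int = 1500,
                      seed: int = 0) -> TreeNode:
    """NJ tree on the full alignment with bootstrap supports on internal edges.

    Retained (post-complete-deletion) columns are resampled with replacement
    ``n_reps`` times; each replicate is rebuilt with p-distance + NJ and the
    support of an internal edge is the percent of replicate trees containing
    its bipartition.
    """
    if n_reps < 1:
        raise ValueError("need at least one bootstrap replicate")
    clean = complete_deletion(aln)
    tree = nj_tree(p_distance_matrix(clean))

    arr = clean.as_array()
    n, L = arr.shape
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    counts: dict[frozenset[str], int] = {}
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        sub = arr[:, cols]
        d = np.zeros((n, n))
        for i in range(n):
            diff = (sub[i] != sub[i + 1:]).mean(axis=1) if i + 1 < n else []
            d[i, i + 1:] = diff
            d[i + 1:, i] = diff
        rep_tree = nj_tree(DistanceMatrix(taxa=list(clean.taxa), values=d, n_sites_used=L))
        for part in bipartitions(rep_tree):
            counts[part] = counts.get(part, 0) + 1

    taxa = frozenset(clean.taxa)
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(t.name for t in node.tips())
        if 2 <= len(side) <= len(taxa) - 2:
            canon = min(side, taxa - side, key=lambda s: tuple(sorted(s)))
            node.support = 100.0 * counts.get(canon, 0) / n_reps
    return tree


# ---------------------------------------------------------------------------
# IO


def read_alignment_fasta(path: str | Path) -> MultipleAlignment:
    """Read an aligned FASTA; rejects ragged rows naming the offending record."""
    taxa, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        taxa.append(rec.id)
        rows.append(str(rec.seq).upper())
    if not taxa:
        raise ValueError(f"no FASTA records in {path}")
    ref = len(rows[0])
    for t, r in zip(taxa, rows):
        if len(r) != ref:
            raise ValueError(f"record {t!r} has length {len(r)}, expected {ref}")
    return MultipleAlignment(taxa=taxa, rows=rows)


def write_alignment_fasta(aln: MultipleAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for t, r in zip(aln.taxa, aln.rows):
            fh.write(f">{t}\n{r}\n")


def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Write Newick with 6-decimal branch lengths and integer support labels."""
    with open(path, "w") as fh:
        fh.write(to_newick(tree) + "\n")


def to_newick(tree: TreeNode) -> str:
    def render(node: TreeNode) -> str:
        if node.is_tip():
            label = node.name or ""
        else:
            inner = ",".join(render(c) for c in node.children)
            support = getattr(node, "support", None)
            label = f"({inner})" + ("" if support is None else str(int(round(support))))
        if node.length is not None:
            label += f":{node.length:.6f}"
        return label

    return render(tree) + ";"


def read_newick(path: str | Path) -> TreeNode:
    """Read Newick; numeric internal-node labels are interpreted as supports."""
    tree = TreeNode.read(str(path), format="newick")
    for node in tree.traverse(include_self=True):
        if not node.is_tip() and node.name is not None:
            try:
                node.support = float(node.name)
            except ValueError:
                pass
            else:
                node.name = None
    return tree


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    dm.to_dataframe().to_csv(path, sep="\t")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(taxa=list(df.index), values=df.to_numpy(dtype=float),
                          n_sites_used=0)
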