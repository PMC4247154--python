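"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from revscreen.phylo import DistanceMatrix


# ---------------------------------------------------------------------------
# random additive (tree-realizable) distance matrices with known topology


def random_additive_matrix(rng: np.random.Generator, n_taxa: int,
                           min_len: float = 0.05, max_len: float = 1.0):
    """Random unrooted binary tree on ``n_taxa`` leaves with random branch lengths.

    Returns ``(DistanceMatrix of exact path lengths, set of nontrivial
    bipartitions of the generating tree)``.  Built by sequential leaf
    insertion into a uniformly chosen existing edge.
    """
    taxa = [f"T{i}" for i in range(n_taxa)]
    next_internal = itertools.count()

    def blen() -> float:
        return float(rng.uniform(min_len, max_len))

    # start from a star on the first three leaves
    center = f"i{next(next_internal)}"
    edges: list[tuple[str, str, float]] = [(center, t, blen()) for t in taxa[:3]]
    for leaf in taxa[3:]:
        k = int(rng.integers(len(edges)))
        u, v, w = edges.pop(k)
        mid = f"i{next(next_internal)}"
        t = float(rng.uniform(0.2, 0.8))
        edges += [(u, mid, w * t), (mid, v, w * (1 - t)), (mid, leaf, blen())]

    adj: dict[str, list[tuple[str, float]]] = {}
    for u, v, w in edges:
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))

    def dists_from(src: str) -> dict[str, float]:
        out = {src: 0.0}
        stack = [src]
        while stack:
            node = stack.pop()
            for nb, w in adj[node]:
                if nb not in out:
                    out[nb] = out[node] + w
                    stack.append(nb)
        return out

    d = np.zeros((n_taxa, n_taxa))
    for i, t in enumerate(taxa):
        all_d = dists_from(t)
        for j, s in enumerate(taxa):
            d[i, j] = all_d[s]
    np.fill_diagonal(d, 0.0)

    # bipartitions: removing each internal edge splits the leaves
    all_set = frozenset(taxa)
    parts = set()
    for u, v, _ in edges:
        if u.startswith("i") and v.startswith("i"):
            # leaves on v's side when the u-v edge is cut
            side = set()
            stack = [v]
            seen = {u, v}
            while stack:
                node = stack.pop()
                if not node.startswith("i"):
                    side.add(node)
                for nb, _w in adj[node]:
                    if nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
            fro = frozenset(side)
            if 2 <= len(fro) <= n_taxa - 2:
                parts.add(min(fro, all_set - fro, key=lambda s: tuple(sorted(s))))
    dm = DistanceMatrix(taxa=taxa, values=(d + d.T) / 2.0, n_sites_used=0)
    return dm, parts


# ---------------------------------------------------------------------------
# exhaustive 4-taxon least-squares oracle


def four_taxon_ls_oracle(dm: DistanceMatrix):
    """Fit all 3 unrooted 4-taxon topologies by least squares.

    Returns ``(best_split, residual)`` where ``best_split`` is the cherry
    pair of the uniquely best-fitting topology as a frozenset of two taxa.
    """
    t = dm.taxa
    assert len(t) == 4
    d = dm.values
    pair_index = {frozenset((i, j)): k for k, (i, j)
                  in enumerate(itertools.combinations(range(4), 2))}
    y = np.array([d[i, j] for i, j in itertools.combinations(range(4), 2)])

    best = None
    for a, b in ((0, 1), (0, 2), (0, 3)):
        c, e = [x for x in range(4) if x not in (a, b)]
        # unknowns: la, lb, lc, le, internal
        X = np.zeros((6, 5))
        ext = {a: 0, b: 1, c: 2, e: 3}
        for (i, j), row in pair_index.items():
            i, j = tuple((i, j))
            X[row, ext[i]] = 1
            X[row, ext[j]] = 1
            same_cherry = {i, j} in ({a, b}, {c, e})
            if not same_cherry:
                X[row, 4] = 1
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = float(np.sum((X @ beta - y) ** 2))
        if best is None or resid < best[1]:
            best = (frozenset((t[a], t[b])), resid)
    return best


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
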