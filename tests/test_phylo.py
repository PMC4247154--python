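"""Complete deletion, p-distance, neighbour joining, bootstrap, newick IO."""

import numpy as np
import pytest
from skbio import DistanceMatrix as SkbioDM
from skbio.tree import nj as skbio_nj

from revscreen.phylo import (
    DistanceMatrix,
    MultipleAlignment,
    bipartitions,
    bootstrap_support,
    complete_deletion,
    nj_tree,
    p_distance_matrix,
    read_alignment_fasta,
    read_newick,
    to_newick,
    write_alignment_fasta,
    write_newick,
)
from conftest import four_taxon_ls_oracle, random_additive_matrix


def aln(taxa_rows: dict[str, str]) -> MultipleAlignment:
    return MultipleAlignment(taxa=list(taxa_rows), rows=list(taxa_rows.values()))


class TestCompleteDeletion:
    def test_gap_free_alignment_unchanged(self):
        a = aln({"A": "MKV", "B": "MKL"})
        assert complete_deletion(a).rows == a.rows

    def test_gapped_and_missing_columns_removed(self):
        a = aln({"A": "MK-VA", "B": "MKLV?", "C": "MKLVA"})
        out = complete_deletion(a)
        # columns 3 (gap in A) and 5 (missing in B) go; order preserved
        assert out.rows == ["MKV", "MKV", "MKV"]
        assert out.length == 3

    def test_all_gap_row_leaves_nothing(self):
        with pytest.raises(ValueError, match="every column"):
            complete_deletion(aln({"A": "---", "B": "MKL"}))


class TestPDistance:
    def test_identical_rows_zero_matrix(self):
        dm = p_distance_matrix(aln({"A": "MKVL", "B": "MKVL"}))
        assert dm.values[0, 1] == 0.0
        assert dm.n_sites_used == 4

    def test_single_difference(self):
        dm = p_distance_matrix(aln({"A": "AAAA", "B": "AAAT"}))
        assert dm.values[0, 1] == pytest.approx(0.25)

    def test_matches_brute_force_column_scan(self, rng):
        """Exact agreement with a per-column mismatch-count oracle on gapped alignments."""
        alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY-"))
        for _ in range(25):
            n, L = int(rng.integers(3, 7)), int(rng.integers(10, 60))
            rows = ["".join(rng.choice(alphabet, L,
                                       p=[0.95 / 20] * 20 + [0.05])) for _ in range(n)]
            taxa = [f"t{i}" for i in range(n)]
            a = MultipleAlignment(taxa=taxa, rows=rows)
            keep = [j for j in range(L)
                    if all(r[j] not in "-.?X" for r in rows)]
            if not keep:
                with pytest.raises(ValueError):
                    p_distance_matrix(a)
                continue
            dm = p_distance_matrix(a)
            assert dm.n_sites_used == len(keep)
            for i in range(n):
                for j in range(n):
                    mism = sum(rows[i][c] != rows[j][c] for c in keep)
                    assert dm.values[i, j] == pytest.approx(mism / len(keep))

    def test_invariant_under_row_reordering(self, rng):
        rows = {"A": "MKVLW", "B": "MKVIW", "C": "MAVIW"}
        d1 = p_distance_matrix(aln(rows))
        d2 = p_distance_matrix(aln(dict(reversed(rows.items()))))
        for i, ti in enumerate(d1.taxa):
            for j, tj in enumerate(d1.taxa):
                assert d1.values[i, j] == d2.values[d2.taxa.index(ti), d2.taxa.index(tj)]


class TestNeighbourJoining:
    def test_two_taxa_midpoint_split(self):
        dm = DistanceMatrix(taxa=["A", "B"], values=np.array([[0, 0.3], [0.3, 0]]))
        tree = nj_tree(dm)
        assert to_newick(tree) == "(A:0.150000,B:0.150000);"

    def test_three_taxon_closed_form(self):
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = nj_tree(DistanceMatrix(taxa=["A", "B", "C"], values=d))
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx((0.3 + 0.5 - 0.6) / 2)
        assert lengths["B"] == pytest.approx((0.3 + 0.6 - 0.5) / 2)
        assert lengths["C"] == pytest.approx((0.5 + 0.6 - 0.3) / 2)

    def test_fewer_than_two_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(taxa=["A"], values=np.zeros((1, 1))))

    def test_four_taxon_additive_recovery_vs_ls_oracle(self, rng):
        """NJ recovers the generating 4-taxon topology; the exhaustive 3-topology
        least-squares oracle confirms it is the unique exact fit."""
        for _ in range(50):
            dm, true_parts = random_additive_matrix(rng, 4)
            (true_split,) = true_parts
            tree = nj_tree(dm)
            assert bipartitions(tree) == {true_split}
            ls_split, resid = four_taxon_ls_oracle(dm)
            assert ls_split == true_split
            assert resid < 1e-18

    def test_additive_recovery_and_exact_path_lengths_up_to_8_taxa(self, rng):
        """Consistency: topology and all pairwise path lengths recovered exactly."""
        for _ in range(60):
            n = int(rng.integers(4, 9))
            dm, true_parts = random_additive_matrix(rng, n)
            tree = nj_tree(dm)
            assert bipartitions(tree) == true_parts
            tt = tree.tip_tip_distances()
            for i, a in enumerate(dm.taxa):
                for j, b in enumerate(dm.taxa):
                    assert tt[a, b] == pytest.approx(dm.values[i, j], abs=1e-9)

    def test_agrees_with_independent_nj_implementation(self, rng):
        """Cross-check topologies against scikit-bio's neighbour joining."""
        for _ in range(20):
            n = int(rng.integers(4, 8))
            dm, _ = random_additive_matrix(rng, n)
            ours = bipartitions(nj_tree(dm))
            theirs = bipartitions(skbio_nj(SkbioDM(dm.values, dm.taxa)))
            assert ours == theirs

    def test_negative_branch_lengths_zeroed_with_sibling_compensation(self):
        # non-additive matrix engineered to produce a negative estimate
        d = np.array([
            [0.0, 0.1, 0.6, 0.6],
            [0.1, 0.0, 0.2, 0.6],
            [0.6, 0.2, 0.0, 0.1],
            [0.6, 0.6, 0.1, 0.0],
        ])
        tree = nj_tree(DistanceMatrix(taxa=list("ABCD"), values=d))
        for node in tree.traverse(include_self=False):
            assert node.length >= 0.0


class TestBootstrap:
    def strong_alignment(self):
        # one informative column (AB vs CD) repeated: every bootstrap
        # replicate resamples an identical alignment
        block = {"A": "K", "B": "K", "C": "R", "D": "R"}
        taxa = list("ABCD")
        rows = [block[t] * 40 for t in taxa]
        return MultipleAlignment(taxa=taxa, rows=rows)

    def test_identical_replicates_give_support_100(self):
        tree = bootstrap_support(self.strong_alignment(), n_reps=25, seed=0)
        supports = [n.support for n in tree.traverse(include_self=False)
                    if not n.is_tip() and hasattr(n, "support")]
        assert supports and all(s == 100.0 for s in supports)

    def test_fixed_seed_reproduces_supports_bit_exactly(self):
        a = self.strong_alignment()
        t1 = bootstrap_support(a, n_reps=50, seed=7)
        t2 = bootstrap_support(a, n_reps=50, seed=7)
        assert to_newick(t1) == to_newick(t2)

    def test_supports_respect_replicate_granularity(self, rng):
        cfg_rows = {"A": "MKVLWAAK", "B": "MKVLWAAR", "C": "MAVIWGGK", "D": "MAVIWGGR"}
        tree = bootstrap_support(aln(cfg_rows), n_reps=8, seed=1)
        for node in tree.traverse(include_self=False):
            s = getattr(node, "support", None)
            if s is not None:
                assert 0.0 <= s <= 100.0
                assert (s * 8 / 100) == pytest.approx(round(s * 8 / 100))


class TestIO:
    def test_newick_round_trip_preserves_splits_lengths_supports(self, tmp_path, rng):
        dm, _ = random_additive_matrix(rng, 10)
        tree = nj_tree(dm)
        for node in tree.traverse(include_self=False):
            if not node.is_tip():
                node.support = 87.0
        path = tmp_path / "tree.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        assert bipartitions(back) == bipartitions(tree)
        tt_a, tt_b = tree.tip_tip_distances(), back.tip_tip_distances()
        for a in dm.taxa:
            for b in dm.taxa:
                assert tt_b[a, b] == pytest.approx(tt_a[a, b], abs=1e-5)
        supports = [n.support for n in back.traverse(include_self=False)
                    if not n.is_tip() and hasattr(n, "support")]
        assert supports and all(s == 87.0 for s in supports)

    def test_fasta_round_trip(self, tmp_path):
        a = aln({"A": "MKV-", "B": "MKVL"})
        path = tmp_path / "aln.fasta"
        write_alignment_fasta(a, path)
        back = read_alignment_fasta(path)
        assert back.taxa == a.taxa and back.rows == a.rows

    def test_ragged_fasta_names_offending_record(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">A\nMKVL\n>B\nMKV\n")
        with pytest.raises(ValueError, match="'B'"):
            read_alignment_fasta(path)
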