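import numpy as np
import pytest

from cystra.align import identity_matrix
from cystra.io import GeneAnnotation, SequenceRecord, revcomp
from cystra.repeats import (
    call_structural_events,
    decompose_cluster,
    group_units,
    nj_tree,
)
from cystra.simulate import ClusterSpec, make_cluster_panel, make_trna_template

from _oracles import random_additive_tree, tree_splits


def tandem_region(unit, n, rid="acc"):
    seq = unit * n
    genes = [
        GeneAnnotation(rid, i * len(unit), i * len(unit) + 72, "+", f"{rid}.g{i+1}",
                       isotype="Cys", anticodon="GCA")
        for i in range(n)
    ]
    return SequenceRecord(rid, seq), genes


class TestDecompose:
    def test_exact_tandem_copies(self, template):
        unit = template[0] + "A" * 348
        region, genes = tandem_region(unit, 4)
        units = decompose_cluster(region, genes)
        assert len(units) == 4
        assert all(u.seq == unit for u in units)
        assert np.allclose(identity_matrix([u.seq for u in units]), 100.0)

    def test_recovers_generator_truth(self, default_panel, decomposed_panel):
        _, units = decomposed_panel
        for acc, pa in default_panel.items():
            assert [(u.start, u.end) for u in units[acc]] == pa.unit_boundaries

    def test_no_genes_errors(self):
        with pytest.raises(ValueError):
            decompose_cluster(SequenceRecord("r", "ACGT" * 100), [])

    def test_reverse_orientation_gives_same_units(self, template):
        unit = template[0] + "GATTACA" * 8  # 72 + 56 = 128 bp units
        region, genes = tandem_region(unit, 3)
        fwd_units = decompose_cluster(region, genes)
        L = len(region.seq)
        rev_region = SequenceRecord("acc", revcomp(region.seq))
        rev_genes = [
            GeneAnnotation("acc", L - g.end, L - g.start, "-", g.gene_id,
                           isotype="Cys", anticodon="GCA")
            for g in genes
        ]
        rev_units = decompose_cluster(rev_region, rev_genes)
        assert [u.seq for u in rev_units] == [u.seq for u in fwd_units]

    def test_even_strand_split_requires_orientation(self):
        region = SequenceRecord("r", "ACGT" * 100)
        genes = [
            GeneAnnotation("r", 0, 72, "+", "a", isotype="Cys", anticodon="GCA"),
            GeneAnnotation("r", 200, 272, "-", "b", isotype="Cys", anticodon="GCA"),
        ]
        with pytest.raises(ValueError, match="orientation"):
            decompose_cluster(region, genes)
        assert len(decompose_cluster(region, genes, orientation="+")) == 2


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        # d(A,B)=2, d(A,C)=4, d(B,C)=4: A and B at 1 each, C at 3
        D = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        tree = nj_tree(D, labels=["A", "B", "C"])
        lengths = {}
        for node, nbrs in tree.adjacency.items():
            for other, l in nbrs:
                lengths[frozenset((node, other))] = l
        inner = [n for n in tree.adjacency if n.startswith("_nj")][0]
        assert lengths[frozenset(("A", inner))] == pytest.approx(1.0, abs=1e-9)
        assert lengths[frozenset(("B", inner))] == pytest.approx(1.0, abs=1e-9)
        assert lengths[frozenset(("C", inner))] == pytest.approx(3.0, abs=1e-9)

    def test_recovers_additive_four_taxon_topologies(self):
        labels = ["A", "B", "C", "D"]
        rng = np.random.default_rng(17)
        for rep in range(15):
            D, true_splits = random_additive_tree(rng, labels)
            M = np.array([[D[u][v] for v in labels] for u in labels])
            tree = nj_tree(M, labels=labels)
            assert tree_splits(tree.adjacency, labels) == true_splits, rep

    def test_recovers_additive_five_taxon_topologies(self):
        labels = list("ABCDE")
        rng = np.random.default_rng(23)
        for rep in range(15):
            D, true_splits = random_additive_tree(rng, labels)
            M = np.array([[D[u][v] for v in labels] for u in labels])
            tree = nj_tree(M, labels=labels)
            assert tree_splits(tree.adjacency, labels) == true_splits, rep

    def test_matches_scikit_bio_topology(self):
        """Dual route: an independent NJ implementation agrees on topology."""
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        labels = list("ABCDEF")
        rng = np.random.default_rng(31)
        for rep in range(5):
            D, _ = random_additive_tree(rng, labels)
            M = np.array([[D[u][v] for v in labels] for u in labels])
            M = (M + M.T) / 2  # path sums can differ in the last float bit
            mine = tree_splits(nj_tree(M, labels=labels).adjacency, labels)
            sk_tree = skbio_nj(DistanceMatrix(M, ids=labels))
            sk_splits = set()
            for node in sk_tree.non_tips(include_self=False):
                side = frozenset(t.name for t in node.tips())
                if 1 < len(side) < len(labels) - 1:
                    comp = frozenset(set(labels) - side)
                    sk_splits.add(min(side, comp, key=sorted))
            assert mine == sk_splits, rep

    def test_degenerate_equal_distances_deterministic(self):
        D = np.ones((4, 4)) - np.eye(4)
        t1 = nj_tree(D, labels=list("ABCD"))
        t2 = nj_tree(D, labels=list("ABCD"))
        assert t1.newick() == t2.newick()
        # lowest-labeled pair joined first
        first_join = t1.adjacency["_nj0"]
        assert {"A", "B"} <= {n for n, _ in first_join}

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1, 2], [1.1, 0, 2], [2, 2, 0]], dtype=float)
        with pytest.raises(ValueError, match="asymmetric"):
            nj_tree(D)

    def test_newick_parses_with_dendropy(self):
        import dendropy

        D = np.array([[0, 2, 4, 5], [2, 0, 4, 5], [4, 4, 0, 3], [5, 5, 3, 0]],
                     dtype=float)
        tree = nj_tree(D, labels=list("ABCD"))
        parsed = dendropy.Tree.get(data=tree.newick(), schema="newick")
        assert {t.taxon.label for t in parsed.leaf_node_iter()} == set("ABCD")


class TestGrouping:
    def test_all_identical_units_one_group(self, decomposed_panel):
        _, units = decomposed_panel
        u = units["Col-like"][0]
        clones = []
        for k in range(4):
            import copy

            c = copy.copy(u)
            c.accession = f"a{k}"
            clones.append(c)
        corr = group_units(clones)
        assert len(set(corr.values())) == 1

    def test_two_divergent_families_split(self, template):
        rng = np.random.default_rng(9)

        def mutate(s, rate):
            out = list(s)
            for i in np.flatnonzero(rng.random(len(out)) < rate):
                out[i] = "ACGT"[("ACGT".index(out[i]) + 1 + rng.integers(3)) % 4]
            return "".join(out)

        base = template[0] + "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200)])
        famA, famB = base, mutate(base, 0.20)
        import copy

        from cystra.repeats import RepeatUnit

        units = []
        for k, fam in enumerate([famA, famA, famB, famB]):
            units.append(
                RepeatUnit(f"a{k}", "c", 1, 0, len(fam), None, mutate(fam, 0.01))
            )
        corr = group_units(units)
        assert len(set(corr.values())) == 2
        assert corr["a0.u1"] == corr["a1.u1"]
        assert corr["a2.u1"] == corr["a3.u1"]

    def test_panel_groups_match_generator_truth(self, default_panel, decomposed_panel):
        _, units = decomposed_panel
        all_units = [u for acc in sorted(units) for u in units[acc]]
        corr = group_units(all_units)
        truth, intact = {}, {}
        for acc, pa in default_panel.items():
            for u, lab, ok in zip(units[acc], pa.unit_groups, pa.unit_intact):
                truth[u.key], intact[u.key] = lab, ok
        # on undamaged units the partition must equal the generator labels
        keys = [k for k in truth if intact[k]]
        for k1 in keys:
            for k2 in keys:
                assert (corr[k1] == corr[k2]) == (truth[k1] == truth[k2]), (k1, k2)
        assert len({corr[k] for k in keys}) == 6


class TestStructuralEvents:
    def test_identical_panels_no_events(self, decomposed_panel):
        regions, units = decomposed_panel
        sub_r = {a: regions[a] for a in ("Col-like", "Est-like")}
        sub_u = {a: units[a] for a in ("Col-like", "Est-like")}
        # Col-like and Est-like have identical structure (both 4 units);
        # only sub-unit-scale divergence separates them -> no events
        events = call_structural_events(sub_r, sub_u, reference="Col-like")
        assert events == []

    def test_insertion_called_against_shorter_reference(self, decomposed_panel):
        regions, units = decomposed_panel
        sub_r = {a: regions[a] for a in ("Col-like", "Ler-like")}
        sub_u = {a: units[a] for a in ("Col-like", "Ler-like")}
        events = call_structural_events(sub_r, sub_u, reference="Col-like")
        assert [e.kind for e in events] == ["whole_unit_insertion"]
        assert events[0].size == 420

    def test_partial_deletion_size_and_units(self, decomposed_panel):
        regions, units = decomposed_panel
        events = call_structural_events(regions, units)
        partial = [e for e in events if e.kind == "partial_deletion"]
        assert len(partial) == 1
        assert partial[0].size == 167
        assert partial[0].accession == "Cvi-like"
        assert partial[0].affected_units == [3, 4]

    def test_whole_unit_deletions_sized_in_unit_multiples(self, decomposed_panel):
        regions, units = decomposed_panel
        events = call_structural_events(regions, units)
        for e in events:
            if e.kind == "whole_unit_deletion":
                assert e.size % 420 == 0
                assert len(e.affected_units) == e.size // 420

    def test_missing_reference_errors(self, decomposed_panel):
        regions, units = decomposed_panel
        with pytest.raises(ValueError, match="absent"):
            call_structural_events(regions, units, reference="nope")
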