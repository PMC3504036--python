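import math

import numpy as np
import pytest

from cleavescan import phylo, synthcohort
from cleavescan.exceptions import SaturationError, ValidationError
from cleavescan.variantmodel import PolymorphismEvent

from conftest import random_seq


def seq_with(base, changes):
    row = list(base)
    for pos, alt in changes:
        row[pos - 1] = alt
    return "".join(row)


class TestK2P:
    def test_identical(self):
        assert phylo.k2p("ACGTACGT", "ACGTACGT") == 0.0

    def test_closed_form_p10_q05(self):
        # 100 sites, 10 transitions (A<->G), 5 transversions (A<->T)
        a = "A" * 100
        b = "G" * 10 + "T" * 5 + "A" * 85
        expected = -0.5 * math.log((1 - 0.2 - 0.05) * math.sqrt(1 - 0.1))
        assert phylo.k2p(a, b) == pytest.approx(expected)
        assert phylo.k2p(a, b) == pytest.approx(0.1702, abs=1e-4)

    def test_transition_only_limit(self):
        a = "A" * 100
        b = "G" * 10 + "A" * 90
        assert phylo.k2p(a, b) == pytest.approx(-0.5 * math.log(0.8))

    def test_symmetry(self, rng):
        a = random_seq(rng, 300)
        b = list(a)
        for p in rng.choice(np.arange(300), size=30, replace=False):
            b[p] = str(rng.choice([x for x in "ACGT" if x != b[p]]))
        b = "".join(b)
        assert phylo.k2p(a, b) == pytest.approx(phylo.k2p(b, a))

    def test_gap_sites_pairwise_deleted(self):
        assert phylo.k2p("ACGT-A", "ACGTCA") == 0.0
        assert phylo.k2p("ACGTNA", "ACGTCA") == 0.0

    def test_zero_iff_identical_over_included_sites(self, rng):
        a = random_seq(rng, 200)
        b = seq_with(a, [(7, {"A": "G"}.get(a[6], "A"))])
        assert phylo.k2p(a, b) > 0.0

    def test_saturation(self):
        with pytest.raises(SaturationError):
            phylo.k2p("A" * 10, "G" * 10)

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            phylo.k2p("ACGT", "ACG")


class TestNJ:
    def test_two_taxa_split_evenly(self):
        dm = phylo.DistanceMatrix(("a", "b"), np.array([[0, 0.4], [0.4, 0]]))
        tree = phylo.nj(dm)
        lengths = dict((c.name, l) for c, l in tree.root.children)
        assert lengths == {"a": pytest.approx(0.2), "b": pytest.approx(0.2)}

    def test_four_taxon_additive_recovery(self):
        # tree ((a:2,b:3):1,(c:4,d:5)); oracle = hand-computed path lengths
        D = np.array(
            [
                [0, 5, 7, 8],
                [5, 0, 8, 9],
                [7, 8, 0, 9],
                [8, 9, 9, 0],
            ],
            dtype=float,
        )
        dm = phylo.DistanceMatrix(("a", "b", "c", "d"), D)
        tree = phylo.nj(dm)
        assert tree.has_clade(["a", "b"])
        recovered = phylo.path_length_matrix(tree)
        order = [recovered.taxa.index(t) for t in dm.taxa]
        np.testing.assert_allclose(recovered.D[np.ix_(order, order)], D, atol=1e-9)

    def test_random_additive_matrices_recovered(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 9))
            taxa = tuple(f"t{i}" for i in range(n))
            # random binary tree via random sequential joins
            D = _random_additive_matrix(rng, n)
            tree = phylo.nj(phylo.DistanceMatrix(taxa, D))
            rec = phylo.path_length_matrix(tree)
            order = [rec.taxa.index(t) for t in taxa]
            np.testing.assert_allclose(rec.D[np.ix_(order, order)], D, atol=1e-9)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValidationError):
            phylo.DistanceMatrix(("a", "b"), np.array([[0, 1], [2, 0]]))

    def test_nan_rejected(self):
        with pytest.raises(ValidationError):
            phylo.DistanceMatrix(("a", "b"), np.array([[0, np.nan], [np.nan, 0]]))

    def test_newick_parses(self):
        import dendropy

        D = _random_additive_matrix(np.random.default_rng(0), 6)
        taxa = tuple(f"t{i}" for i in range(6))
        tree = phylo.nj(phylo.DistanceMatrix(taxa, D))
        parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        assert {leaf.taxon.label for leaf in parsed.leaf_node_iter()} == set(taxa)

    def test_matches_reference_implementation(self, rng):
        # cross-check path-length matrices against scikit-bio's NJ
        import io as _io

        import skbio

        D = _random_additive_matrix(rng, 7)
        taxa = [f"t{i}" for i in range(7)]
        ours = phylo.nj(phylo.DistanceMatrix(tuple(taxa), D))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(D, ids=taxa))
        ours_pl = phylo.path_length_matrix(ours)
        order = [ours_pl.taxa.index(t) for t in taxa]
        for i, a in enumerate(taxa):
            for j, b in enumerate(taxa):
                if i < j:
                    assert ours_pl.D[order[i], order[j]] == pytest.approx(
                        theirs.find(a).distance(theirs.find(b)), abs=1e-6
                    )


def _random_additive_matrix(rng, n):
    """Path-length matrix of a random binary tree with positive edges."""
    # build a random tree over taxa indices, then measure path lengths
    nodes = {i: [] for i in range(n)}  # adjacency: node -> [(nbr, w)]
    next_id = n
    active = list(range(n))
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[i], active[j]
        u = next_id
        next_id += 1
        wa, wb = rng.uniform(0.5, 3.0, size=2)
        nodes.setdefault(u, [])
        nodes[u] += [(a, wa), (b, wb)]
        nodes[a].append((u, wa))
        nodes[b].append((u, wb))
        active = [x for x in active if x not in (a, b)] + [u]
    D = np.zeros((n, n))
    for s in range(n):
        dist = {s: 0.0}
        stack = [s]
        while stack:
            v = stack.pop()
            for w, weight in nodes[v]:
                if w not in dist:
                    dist[w] = dist[v] + weight
                    stack.append(w)
        for t in range(n):
            D[s, t] = dist[t]
    return (D + D.T) / 2.0


class TestBootstrap:
    def test_identical_sequences_star(self):
        aln = {f"s{i}": "ACGTACGTAC" for i in range(6)}
        tree = phylo.bootstrap_support(aln, n_reps=20, seed=1)
        assert tree.bipartitions() == set()
        assert all(v == 0 for v in tree.supports.values())

    def test_two_groups_fully_supported(self, rng):
        base = random_seq(rng, 300)
        other = list(base)
        for p in rng.choice(np.arange(1, 301), size=50, replace=False):
            other[p - 1] = {"A": "G", "G": "A", "C": "T", "T": "C"}[other[p - 1]]
        other = "".join(other)
        aln = {f"a{i}": base for i in range(10)} | {f"b{i}": other for i in range(10)}
        tree = phylo.bootstrap_support(aln, n_reps=100, seed=3)
        group = [f"a{i}" for i in range(10)]
        assert tree.has_clade(group)
        assert tree.support_for(group) == 100

    def test_seed_determinism(self, rng):
        base = random_seq(rng, 120)
        aln = {
            "a": base,
            "b": seq_with(base, [(5, "A" if base[4] != "A" else "C")]),
            "c": seq_with(base, [(50, "G" if base[49] != "G" else "C")]),
            "d": seq_with(base, [(5, "A" if base[4] != "A" else "C"),
                                 (90, "T" if base[89] != "T" else "C")]),
        }
        t1 = phylo.bootstrap_support(aln, n_reps=50, seed=9)
        t2 = phylo.bootstrap_support(aln, n_reps=50, seed=9)
        assert t1.supports == t2.supports
        assert t1.to_newick() == t2.to_newick()

    def test_input_order_invariance(self, rng):
        base = random_seq(rng, 150)
        variants = {
            "a": base,
            "b": seq_with(base, [(10, "A" if base[9] != "A" else "C")]),
            "c": seq_with(base, [(60, "A" if base[59] != "A" else "C")]),
            "d": seq_with(base, [(100, "A" if base[99] != "A" else "C")]),
        }
        t1 = phylo.bootstrap_support(variants, n_reps=30, seed=5)
        reordered = {k: variants[k] for k in ["d", "b", "a", "c"]}
        t2 = phylo.bootstrap_support(reordered, n_reps=30, seed=5)
        assert t1.supports == t2.supports

    def test_replicate_count_validated(self):
        with pytest.raises(ValidationError):
            phylo.bootstrap_support({"a": "ACGT", "b": "ACGT"}, n_reps=0)


class TestAlignmentAssembly:
    def test_single_gene_identity(self):
        aln = {"g": {"s1": "ACGT", "s2": "ACGA"}}
        combined, parts = phylo.concat_alignment(aln)
        assert combined == aln["g"]
        assert parts == [("g", 1, 4)]

    def test_concatenation_lengths(self, fixtures):
        refs = synthcohort.references_for_events(
            fixtures.panel_events, fixtures.panel_gene_lengths, seed=1
        )
        samples = [f"B{i}" for i in range(1, 97)]
        by_sg = {}
        for e in fixtures.panel_events:
            by_sg.setdefault(e.gene, {}).setdefault(e.sample, []).append(e)
        per_gene = {
            gene: phylo.reconstruct_haplotypes(refs[gene], by_sg.get(gene, {}), samples)
            for gene in ("accD", "matK", "rbcL")
        }
        combined, parts = phylo.concat_alignment(per_gene)
        assert all(len(s) == 1470 + 1575 + 1440 for s in combined.values())
        assert parts == [("accD", 1, 1470), ("matK", 1471, 3045), ("rbcL", 3046, 4485)]
        # deletion carriers get gap columns at the deleted positions
        assert combined["B11"][559:565] == "------"
        assert "-" not in combined["B76"][559:565]

    def test_missing_sample_rejected(self):
        with pytest.raises(ValidationError):
            phylo.concat_alignment(
                {"g1": {"s1": "AC"}, "g2": {"s1": "AC", "s2": "GT"}}
            )

    def test_insertions_rejected_in_reconstruction(self):
        event = PolymorphismEvent("s1", "g", 2, "insertion", "", "AA")
        with pytest.raises(ValidationError):
            phylo.reconstruct_haplotypes("ACGT", {"s1": [event]}, ["s1"])


class TestPanelTree:
    @pytest.fixture()
    def panel_alignment(self, fixtures):
        refs = synthcohort.references_for_events(
            fixtures.panel_events, fixtures.panel_gene_lengths, seed=42
        )
        samples = [f"B{i}" for i in range(1, 97)]
        by_gene = {}
        for e in fixtures.panel_events:
            by_gene.setdefault(e.gene, {}).setdefault(e.sample, []).append(e)
        per_gene = {
            gene: phylo.reconstruct_haplotypes(refs[gene], by_gene.get(gene, {}), samples)
            for gene in ("accD", "matK", "rbcL")
        }
        combined, _ = phylo.concat_alignment(per_gene)
        return combined

    def test_b94_b96_trio_forms_clade(self, panel_alignment):
        tree = phylo.nj(phylo.k2p_matrix(panel_alignment))
        assert tree.has_clade(["B94", "B95", "B96"])
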