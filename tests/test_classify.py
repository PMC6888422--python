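"""Alignment, distances, neighbor joining, bootstrap and group assignment."""

import itertools
import math

import numpy as np
import pytest

from sawrky import classify as cl
from sawrky import synthetic_data as syn
from sawrky.family_id import DomainHit, DomainAnnotation, ZincFingerPattern

PARAMS = cl.AlignParams()


def enumerate_alignment_score(a, b, params=PARAMS):
    """Exhaustive recursion over all global alignments (affine gaps: a gap
    of length k costs open + (k-1)*extend). Independent of the aligner."""
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load(params.matrix)

    def rec(i, j, state):
        if i == len(a) and j == len(b):
            return 0.0
        best = -math.inf
        if i < len(a) and j < len(b):
            best = max(best, mat[a[i], b[j]] + rec(i + 1, j + 1, "m"))
        if i < len(a):
            cost = params.gap_extend if state == "ga" else params.gap_open
            best = max(best, cost + rec(i + 1, j, "ga"))
        if j < len(b):
            cost = params.gap_extend if state == "gb" else params.gap_open
            best = max(best, cost + rec(i, j + 1, "gb"))
        return best

    return rec(0, 0, "m")


class TestGlobalAlign:
    def test_identical_sequences_identity_one(self):
        (ga, gb), ident = cl.global_align("MKVLAN", "MKVLAN")
        assert ident == 1.0
        assert ga == gb == "MKVLAN"

    def test_single_mismatch_identity_zero(self):
        _, ident = cl.global_align("A", "G")
        assert ident == 0.0

    def test_score_matches_exhaustive_enumeration(self):
        """Optimal score equals brute-force enumeration over all global
        alignments for random short peptides."""
        rng = np.random.default_rng(17)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        pairs = [
            (
                "".join(rng.choice(aa, size=rng.integers(1, 7))),
                "".join(rng.choice(aa, size=rng.integers(1, 7))),
            )
            for _ in range(15)
        ]
        pairs += [("WRKYGQK", "WRKYGKK"), ("MKVLANQR", "MKLANQR")]
        for a, b in pairs:
            assert cl.alignment_score(a, b) == pytest.approx(
                enumerate_alignment_score(a, b)
            )


class TestCenterStarMsa:
    def test_identical_sequences_gap_free(self):
        msa = cl.center_star_msa(["MKVLAN"] * 3)
        assert all(r == "MKVLAN" for r in msa.rows)

    def test_substring_padded_with_end_gaps(self):
        msa = cl.center_star_msa(
            ["MKVLANQERST", "MKVLANQERST", "MKVLANQ"], ids=["a", "b", "c"]
        )
        row_c = msa.rows[2]
        assert row_c.replace("-", "") == "MKVLANQ"
        assert row_c == "MKVLANQ" + "-" * (msa.n_columns - 7)

    def test_ungapping_reproduces_inputs(self):
        rng = np.random.default_rng(23)
        aa = list("ACDEFGHIKLMNPQRSTVWY")
        seqs = ["".join(rng.choice(aa, size=rng.integers(10, 30))) for _ in range(5)]
        msa = cl.center_star_msa(seqs)
        for row, seq in zip(msa.rows, seqs):
            assert row.replace("-", "") == seq

    def test_fewer_than_two_sequences_is_error(self):
        with pytest.raises(ValueError):
            cl.center_star_msa(["MKV"])


class TestDistanceMatrix:
    def test_identical_rows_zero(self):
        msa = cl.Msa(ids=("a", "b"), rows=("MKVLAN", "MKVLAN"))
        D = cl.distance_matrix(msa, "p_distance")
        assert D.matrix[0, 1] == 0.0

    def test_p_distance_definition(self):
        msa = cl.Msa(ids=("a", "b"), rows=("AAAAAAAAAA", "AAAAAAAAGG"))
        D = cl.distance_matrix(msa, "p_distance")
        assert D.matrix[0, 1] == pytest.approx(0.2)

    def test_poisson_closed_form(self):
        msa = cl.Msa(ids=("a", "b"), rows=("AAAAAAAAAA", "AAAAAAAAGG"))
        D = cl.distance_matrix(msa, "poisson")
        assert D.matrix[0, 1] == pytest.approx(-math.log(0.8))

    def test_complete_deletion_drops_gapped_columns(self):
        msa = cl.Msa(ids=("a", "b"), rows=("MK-LAN", "MKVLGN"))
        D = cl.distance_matrix(msa, "p_distance")
        assert D.matrix[0, 1] == pytest.approx(1 / 5)

    def test_saturated_poisson_is_error(self):
        msa = cl.Msa(ids=("a", "b"), rows=("AAAA", "GGGG"))
        with pytest.raises(ValueError, match="[Ss]aturated|p = 1"):
            cl.distance_matrix(msa, "poisson")


def random_additive_tree(n, rng):
    """Random binary tree with uniform branch lengths; returns the
    leaf-path distance matrix (the additivity oracle)."""
    import itertools as it

    nodes = {i: None for i in range(n)}
    adj = {}

    def add_edge(u, v, w):
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))

    avail = list(range(n))
    next_id = n
    while len(avail) > 1:
        i, j = rng.choice(len(avail), size=2, replace=False)
        u, v = avail[int(i)], avail[int(j)]
        add_edge(u, next_id, float(rng.uniform(0.5, 3.0)))
        add_edge(v, next_id, float(rng.uniform(0.5, 3.0)))
        avail = [x for x in avail if x not in (u, v)] + [next_id]
        next_id += 1
    D = np.zeros((n, n))
    for leaf in range(n):
        dist = {leaf: 0.0}
        stack = [leaf]
        while stack:
            cur = stack.pop()
            for nb, w in adj[cur]:
                if nb not in dist:
                    dist[nb] = dist[cur] + w
                    stack.append(nb)
        for other in range(n):
            D[leaf, other] = dist[other]
    return D


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = cl.DistanceMatrix(
            ids=("A", "B", "C"),
            matrix=np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float),
        )
        tree = cl.neighbor_joining(D)
        # l_A = (3+4-5)/2 = 1, l_B = 2, l_C = 3
        lengths = {}
        for child, bl in tree.root.children:
            lengths[child.label] = bl
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_four_taxon_additive_recovery(self):
        # tree ((A:2,B:3):1,(C:4,D:5)) gives these path distances
        D = np.array(
            [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]], float
        )
        tree = cl.neighbor_joining(
            cl.DistanceMatrix(ids=("A", "B", "C", "D"), matrix=D)
        )
        assert frozenset(
            {frozenset({"A", "B"}), frozenset({"C", "D"})}
        ) in tree.bipartitions()
        ids, P = tree.path_lengths()
        assert np.allclose(P, D, atol=1e-9)

    @pytest.mark.parametrize("n", [5, 6, 8])
    def test_random_additive_matrices_exact(self, n):
        """NJ reconstructs random additive matrices exactly: the tree's
        path-length matrix equals the input within 1e-9."""
        rng = np.random.default_rng(100 + n)
        for _ in range(5):
            D = random_additive_tree(n, rng)
            ids = tuple(f"t{i}" for i in range(n))
            tree = cl.neighbor_joining(cl.DistanceMatrix(ids=ids, matrix=D))
            got_ids, P = tree.path_lengths()
            order = [got_ids.index(i) for i in ids]
            assert np.allclose(P[np.ix_(order, order)], D, atol=1e-9)

    def test_topology_agrees_with_independent_nj(self):
        """Cross-check topology against scikit-bio's neighbor joining on a
        random non-additive matrix."""
        import skbio

        rng = np.random.default_rng(5)
        n = 6
        M = rng.uniform(0.1, 1.0, size=(n, n))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0.0)
        ids = tuple(f"t{i}" for i in range(n))
        ours = cl.neighbor_joining(cl.DistanceMatrix(ids=ids, matrix=D))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(D, ids=list(ids)))
        their_bp = set()
        all_ids = frozenset(ids)
        for node in theirs.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 2 <= len(side) <= n - 2:
                their_bp.add(frozenset({side, all_ids - side}))
        assert ours.bipartitions() == their_bp

    def test_too_few_taxa_is_error(self):
        D = cl.DistanceMatrix(
            ids=("A", "B"), matrix=np.array([[0, 1], [1, 0]], float)
        )
        with pytest.raises(ValueError):
            cl.neighbor_joining(D)


CLEAN_MSA = cl.Msa(
    ids=("a1", "a2", "b1", "b2"),
    rows=(
        "AAAAAAAAAAKKKKKKKKKK",
        "AAAAAAAAAAKKKKKKKKKR",
        "DDDDDDDDDDKKKKKKKKKK",
        "DDDDDDDDDDKKKKKKKKKR",
    ),
)


class TestBootstrap:
    def test_clean_split_has_high_support(self):
        tree = cl.bootstrap_support(CLEAN_MSA, model="p_distance", reps=200, seed=3)
        supports = [node.support for node, _ in tree.internal_edges()]
        assert supports and min(supports) > 95

    def test_supports_in_range_and_deterministic(self):
        t1 = cl.bootstrap_support(CLEAN_MSA, model="p_distance", reps=50, seed=7)
        t2 = cl.bootstrap_support(CLEAN_MSA, model="p_distance", reps=50, seed=7)
        s1 = [n.support for n, _ in t1.internal_edges()]
        s2 = [n.support for n, _ in t2.internal_edges()]
        assert s1 == s2
        assert all(0 <= s <= 100 for s in s1)

    def test_supports_invariant_to_leaf_order(self):
        perm = cl.Msa(
            ids=tuple(CLEAN_MSA.ids[i] for i in (2, 0, 3, 1)),
            rows=tuple(CLEAN_MSA.rows[i] for i in (2, 0, 3, 1)),
        )
        t1 = cl.bootstrap_support(CLEAN_MSA, model="p_distance", reps=100, seed=5)
        t2 = cl.bootstrap_support(perm, model="p_distance", reps=100, seed=5)

        def support_map(t):
            return {bp: n.support for n, bp in t.internal_edges()}

        assert support_map(t1) == support_map(t2)


def _annotation(n_hits, zinc_type):
    finger = ZincFingerPattern(10, 16, 40, 42, zinc_type[-1]) if zinc_type != "undetected" else None
    hits = tuple(
        DomainHit(hepta_start=i * 60, hepta_seq="WRKYGQK", finger=finger)
        for i in range(n_hits)
    )
    return DomainAnnotation(
        protein_id="p", length_aa=300, hits=hits, zinc_type=zinc_type
    )


class TestAssignGroup:
    @pytest.mark.parametrize(
        "n_hits,zinc_type,expected",
        [
            (2, "C-C-H-H", "I"),
            (3, "C-C-H-C", "I"),
            (1, "C-C-H-H", "II"),
            (1, "C-C-H-C", "III"),
            (1, "C-C-H-T", "unresolved"),
            (1, "C-C-H-Y", "unresolved"),
            (1, "undetected", "unresolved"),
        ],
    )
    def test_truth_table(self, n_hits, zinc_type, expected):
        assert cl.assign_group(_annotation(n_hits, zinc_type)) == expected

    def test_no_domain_is_error(self):
        with pytest.raises(ValueError):
            cl.assign_group(_annotation(0, "undetected"))


class TestAssignSubgroup:
    def _tree(self):
        # ((Q:1,(R1:1,R2:1):1):1,(R3:1,R4:1):1);  R1,R2=IIa; R3=IId, R4=IIb
        q = cl.Node(label="Q")
        r1, r2, r3, r4 = (cl.Node(label=f"R{i}") for i in range(1, 5))
        inner = cl.Node(children=[(r1, 1.0), (r2, 1.0)])
        left = cl.Node(children=[(q, 1.0), (inner, 1.0)])
        right = cl.Node(children=[(r3, 1.0), (r4, 1.0)])
        return cl.Tree(root=cl.Node(children=[(left, 1.0), (right, 1.0)]))

    def test_unanimous_nearest_clade(self):
        labels = {"R1": "IIa", "R2": "IIa", "R3": "IId", "R4": "IIb"}
        label, basis = cl.assign_subgroup("Q", self._tree(), labels)
        assert (label, basis) == ("IIa", "phylogeny")

    def test_mixed_clade_falls_back_to_nearest_reference(self):
        # make the nearest references disagree; patristic distance decides
        q = cl.Node(label="Q")
        r1 = cl.Node(label="R1")
        r2 = cl.Node(label="R2")
        hub = cl.Node(children=[(q, 1.0), (r1, 0.5), (r2, 2.0)])
        tree = cl.Tree(root=hub)
        labels = {"R1": "IId", "R2": "IIe"}
        label, basis = cl.assign_subgroup("Q", tree, labels)
        assert (label, basis) == ("IId", "phylogeny_nearest")

    def test_no_references_is_error(self):
        with pytest.raises(ValueError):
            cl.assign_subgroup("Q", self._tree(), {"Z9": "IIa"})

    def test_planted_subgroup_recovery(self):
        """End-to-end placement: at least 95% of synthetic queries recover
        their planted subgroup through MSA → distances → NJ → placement."""
        bench = syn.gen_subgroup_benchmark(seed=7)
        ids = sorted(bench.sequences)
        msa = cl.center_star_msa([bench.sequences[i] for i in ids], ids=ids)
        tree = cl.neighbor_joining(cl.distance_matrix(msa, "poisson"))
        hits = sum(
            cl.assign_subgroup(q, tree, bench.reference_labels)[0] == truth
            for q, truth in bench.query_truth.items()
        )
        assert hits / len(bench.query_truth) >= 0.95


class TestSummarizeFamily:
    def test_single_row(self, family_rows):
        row = next(r for r in family_rows if r.gene == "SaWRKY1")
        s = cl.summarize_family([row])
        assert s.orf_min == s.orf_max == s.orf_mean == 333
        assert s.n_total == 1

    def test_fixture_counts(self, family_rows):
        s = cl.summarize_family(family_rows)
        assert s.n_total == 64
        assert s.orf_min == 121 and s.orf_max == 764
        assert s.group_counts == {"I": 15, "II": 43, "III": 6}
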