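"""Phylogenetic classification of WRKY proteins.

Groups I/II/III follow from domain count and zinc-finger type: two WRKY
domains → group I; one domain with a C-C-H-H finger → group II; one domain
with the C-C-H-C finger → group III. Subgroups IIa-IIe are clades, so they
are assigned by placement in a neighbor-joining tree against labeled
reference domains.

Distances come from a center-star multiple alignment with complete deletion
of gapped columns, under either the p-distance or the Poisson-corrected
model d = -ln(1 - p). The NJ implementation is the Saitou-Nei algorithm
with deterministic lexicographic tie-breaks and MEGA-style clamping of
negative branch-length estimates (deficit moved to the sibling edge).
Bootstrap support resamples alignment columns with replacement and reports
the percentage of replicate trees containing each bipartition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .family_id import DomainAnnotation

# ---------------------------------------------------------------------------
# Pairwise alignment


@dataclass(frozen=True)
class AlignParams:
    """Global-alignment scoring: substitution matrix name plus affine gap
    penalties. A gap of length k costs ``gap_open + (k-1) * gap_extend``."""

    matrix: str = "BLOSUM62"
    gap_open: float = -10.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")


def _make_aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def global_align(
    a: str, b: str, params: AlignParams = AlignParams()
) -> tuple[tuple[str, str], float]:
    """Needleman-Wunsch optimal global alignment of two protein sequences.

    Returns the gapped pair and the identity fraction
    (matches / alignment columns). Delegates the dynamic programming to
    Biopython's PairwiseAligner.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aligner = _make_aligner(params)
    aln = aligner.align(a, b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    identity = sum(x == y for x, y in zip(ga, gb)) / len(ga)
    return (ga, gb), identity


def alignment_score(a: str, b: str, params: AlignParams = AlignParams()) -> float:
    """Optimal global alignment score under ``params``."""
    return _make_aligner(params).score(a, b)


# ---------------------------------------------------------------------------
# Center-star MSA


@dataclass(frozen=True)
class Msa:
    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("Msa rows must have equal length")
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def center_star_msa(
    sequences: Sequence[str],
    params: AlignParams = AlignParams(),
    ids: Optional[Sequence[str]] = None,
) -> Msa:
    """Center-star progressive alignment.

    The center is the sequence minimizing the sum of pairwise distances
    (1 - identity); every other sequence is aligned pairwise to the center
    and gaps are merged under "once a gap, always a gap".
    """
    n = len(sequences)
    if n < 2:
        raise ValueError("center_star_msa needs at least 2 sequences")
    if ids is None:
        ids = [f"seq{i}" for i in range(n)]

    dist_sum = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            _, ident = global_align(sequences[i], sequences[j], params)
            d = 1.0 - ident
            dist_sum[i] += d
            dist_sum[j] += d
    center = int(np.argmin(dist_sum))
    c = sequences[center]
    nc = len(c)

    # inserts[k][i] = gaps alignment k opens before center residue i
    pair_alns: list[tuple[str, str]] = []
    inserts: list[np.ndarray] = []
    for j in range(n):
        if j == center:
            continue
        (gc, gs), _ = global_align(c, sequences[j], params)
        ins = np.zeros(nc + 1, dtype=int)
        pos = 0
        for col in range(len(gc)):
            if gc[col] == "-":
                ins[pos] += 1
            else:
                pos += 1
        pair_alns.append((gc, gs))
        inserts.append(ins)
    master = (
        np.max(np.stack(inserts), axis=0) if inserts else np.zeros(nc + 1, int)
    )

    def expand(gc: str, gs: str, ins: np.ndarray) -> str:
        # pad each inter-residue slot of this pairwise alignment out to the
        # master gap count (extra gaps appended after the slot's own columns)
        out = []
        pos = 0
        col = 0
        for pos in range(nc + 1):
            own = ins[pos]
            for _ in range(own):
                out.append(gs[col])
                col += 1
            out.append("-" * int(master[pos] - own))
            if pos < nc:
                out.append(gs[col])
                col += 1
        return "".join(out)

    center_row = []
    for pos in range(nc + 1):
        center_row.append("-" * int(master[pos]))
        if pos < nc:
            center_row.append(c[pos])
    rows: list[str] = []
    k = 0
    for j in range(n):
        if j == center:
            rows.append("".join(center_row))
        else:
            gc, gs = pair_alns[k]
            rows.append(expand(gc, gs, inserts[k]))
            k += 1
    return Msa(ids=tuple(ids), rows=tuple(rows))


# ---------------------------------------------------------------------------
# Distances


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("diagonal must be zero")
        if (m < -1e-12).any():
            raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.ids)


def distance_matrix(msa: Msa, model: str = "poisson") -> DistanceMatrix:
    """Pairwise distances after complete deletion of gapped columns.

    ``p_distance`` is the mismatch proportion p; ``poisson`` applies the
    correction d = -ln(1 - p), which diverges at p = 1 (raised as an error).
    """
    if model not in {"p_distance", "poisson"}:
        raise ValueError(f"unknown model {model!r}")
    keep = [
        col
        for col in range(msa.n_columns)
        if all(row[col] != "-" for row in msa.rows)
    ]
    if not keep:
        raise ValueError("no gap-free columns after complete deletion")
    n = len(msa.rows)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mism = sum(msa.rows[i][c] != msa.rows[j][c] for c in keep)
            p = mism / len(keep)
            if model == "poisson":
                if p >= 1.0:
                    raise ValueError(
                        "saturated pair (p = 1): Poisson distance undefined"
                    )
                d = -math.log(1.0 - p)
            else:
                d = p
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(ids=msa.ids, matrix=mat)


# ---------------------------------------------------------------------------
# Trees


class Node:
    """Tree node; ``children`` is a list of (child, branch_length)."""

    __slots__ = ("label", "children", "support")

    def __init__(self, label=None, children=None, support=None):
        self.label = label
        self.children: list[tuple[Node, float]] = children or []
        self.support: Optional[int] = support

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf():
            return [self]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def leaf_labels(self) -> frozenset[str]:
        return frozenset(l.label for l in self.leaves())


@dataclass
class Tree:
    """Unrooted tree stored with an arbitrary root; supports are integer
    percentages attached to internal nodes."""

    root: Node

    @property
    def leaf_labels(self) -> frozenset[str]:
        return self.root.leaf_labels()

    def to_newick(self) -> str:
        def fmt(node: Node, length: Optional[float]) -> str:
            if node.is_leaf():
                body = node.label
            else:
                inner = ",".join(fmt(c, bl) for c, bl in node.children)
                sup = "" if node.support is None else str(node.support)
                body = f"({inner}){sup}"
            return body if length is None else f"{body}:{length:.9g}"

        return fmt(self.root, None) + ";"

    def bipartitions(self) -> set[frozenset[frozenset[str]]]:
        """Non-trivial bipartitions as {side, complement} pairs."""
        all_leaves = self.leaf_labels
        out = set()

        def walk(node: Node):
            for child, _ in node.children:
                side = child.leaf_labels()
                if 2 <= len(side) <= len(all_leaves) - 2:
                    out.add(frozenset({side, all_leaves - side}))
                walk(child)

        walk(self.root)
        return out

    def internal_edges(self) -> list[tuple[Node, frozenset[frozenset[str]]]]:
        all_leaves = self.leaf_labels
        out = []

        def walk(node: Node):
            for child, _ in node.children:
                side = child.leaf_labels()
                if 2 <= len(side) <= len(all_leaves) - 2:
                    out.append((child, frozenset({side, all_leaves - side})))
                walk(child)

        walk(self.root)
        return out

    def adjacency(self) -> dict[Node, list[tuple[Node, float]]]:
        adj: dict[Node, list[tuple[Node, float]]] = {}

        def walk(node: Node):
            adj.setdefault(node, [])
            for child, bl in node.children:
                adj[node].append((child, bl))
                adj.setdefault(child, []).append((node, bl))
                walk(child)

        walk(self.root)
        return adj

    def path_lengths(self) -> tuple[list[str], np.ndarray]:
        """Leaf-to-leaf patristic distance matrix (ids sorted)."""
        adj = self.adjacency()
        leaves = sorted(self.root.leaves(), key=lambda n: n.label)
        ids = [l.label for l in leaves]
        n = len(leaves)
        mat = np.zeros((n, n))
        for i, leaf in enumerate(leaves):
            dist = {leaf: 0.0}
            stack = [leaf]
            while stack:
                cur = stack.pop()
                for nb, bl in adj[cur]:
                    if nb not in dist:
                        dist[nb] = dist[cur] + bl
                        stack.append(nb)
            for j, other in enumerate(leaves):
                mat[i, j] = dist[other]
        return ids, mat


def neighbor_joining(D: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining.

    At each step the pair minimizing
    Q(i,j) = (n-2) d(i,j) - r_i - r_j is joined (ties broken by the
    lexicographically smallest pair of cluster keys, a cluster's key being
    its smallest leaf label). Branch lengths use the standard NJ formulas;
    a negative estimate is clamped to zero with the deficit moved to the
    sibling edge so the pair's total is preserved.
    """
    n = len(D)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[Node] = [Node(label=i) for i in D.ids]
    keys: list[str] = list(D.ids)
    d = D.matrix.astype(float).copy()
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = tuple(sorted((keys[i], keys[j])))
                if best is None or (q, key) < (best[0], best[1]):
                    best = (q, key, i, j)
        _, _, i, j = best
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        if li < 0:
            li, lj = 0.0, d[i, j]
        elif lj < 0:
            lj, li = 0.0, d[i, j]
        u = Node(children=[(nodes[i], li), (nodes[j], lj)])
        # reuse slot i for the new cluster
        for k in active:
            if k in (i, j):
                continue
            duk = max(0.0, (d[i, k] + d[j, k] - d[i, j]) / 2.0)
            d[i, k] = d[k, i] = duk
        nodes[i] = u
        keys[i] = min(keys[i], keys[j])
        active.remove(j)

    i, j = active
    a, b = nodes[i], nodes[j]
    if a.is_leaf() and not b.is_leaf():
        a, b = b, a
    a.children.append((b, d[i, j]))
    return Tree(root=a)


def bootstrap_support(
    msa: Msa,
    model: str = "poisson",
    reps: int = 1000,
    seed: int = 0,
) -> Tree:
    """NJ tree from the full alignment with bootstrap supports.

    Columns are resampled with replacement ``reps`` times; the support of
    each internal edge is the percentage of replicate trees containing the
    same bipartition. Deterministic for a given seed.
    """
    ref = neighbor_joining(distance_matrix(msa, model))
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {}
    ncol = msa.n_columns
    for _ in range(reps):
        cols = rng.integers(0, ncol, size=ncol)
        rows = tuple("".join(row[c] for c in cols) for row in msa.rows)
        rep_msa = Msa(ids=msa.ids, rows=rows)
        rep_tree = neighbor_joining(distance_matrix(rep_msa, model))
        for bp in rep_tree.bipartitions():
            counts[bp] = counts.get(bp, 0) + 1
    for node, bp in ref.internal_edges():
        node.support = round(100.0 * counts.get(bp, 0) / reps)
    return ref


# ---------------------------------------------------------------------------
# Group / subgroup assignment


@dataclass(frozen=True)
class GroupAssignment:
    gene: str
    group: str
    subgroup: str = "none"
    basis: str = "rule"

    def __post_init__(self) -> None:
        if self.subgroup != "none" and self.group != "II":
            raise ValueError("subgroup requires group II")


def assign_group(annotation: DomainAnnotation) -> str:
    """Rule-based major group: two or more WRKY domains → I; one domain
    with C-C-H-H → II; one with C-C-H-C → III; variant or undetected
    finger types are ``unresolved`` (deferred to phylogenetic placement)."""
    if annotation.n_domains == 0:
        raise ValueError(
            f"{annotation.protein_id}: no WRKY domain; not a family member"
        )
    if annotation.n_domains >= 2:
        return "I"
    if annotation.zinc_type == "C-C-H-H":
        return "II"
    if annotation.zinc_type == "C-C-H-C":
        return "III"
    return "unresolved"


def assign_subgroup(
    query_id: str,
    tree: Tree,
    reference_labels: Mapping[str, str],
) -> tuple[str, str]:
    """Place a query leaf among labeled reference leaves.

    Walking outward from the query by topological distance, the nearest
    non-empty set of references decides if unanimous; otherwise the label
    of the reference at minimum patristic distance is used (fallback
    basis). Returns ``(label, basis)`` with basis ``phylogeny`` or
    ``phylogeny_nearest``.
    """
    refs_in_tree = set(reference_labels) & set(tree.leaf_labels)
    if not refs_in_tree:
        raise ValueError("tree contains no labeled reference leaves")
    adj = tree.adjacency()
    query = next(
        (l for l in tree.root.leaves() if l.label == query_id), None
    )
    if query is None:
        raise ValueError(f"query {query_id!r} not in tree")

    # breadth-first rings by edge count; track patristic distance too
    from collections import deque

    edge_dist = {query: 0}
    path_len = {query: 0.0}
    queue = deque([query])
    while queue:
        cur = queue.popleft()
        for nb, bl in adj[cur]:
            if nb not in edge_dist:
                edge_dist[nb] = edge_dist[cur] + 1
                path_len[nb] = path_len[cur] + bl
                queue.append(nb)

    ref_leaves = [
        l for l in tree.root.leaves() if l.label in refs_in_tree
    ]
    by_ring: dict[int, list[Node]] = {}
    for leaf in ref_leaves:
        by_ring.setdefault(edge_dist[leaf], []).append(leaf)
    nearest_ring = min(by_ring)
    labels = {reference_labels[l.label] for l in by_ring[nearest_ring]}
    if len(labels) == 1:
        return labels.pop(), "phylogeny"
    best = min(ref_leaves, key=lambda l: (path_len[l], l.label))
    return reference_labels[best.label], "phylogeny_nearest"


# ---------------------------------------------------------------------------
# Family summary


@dataclass(frozen=True)
class FamilySummary:
    n_total: int
    n_two_domain: int
    zinc_type_counts: dict[str, int]
    group_counts: dict[str, int]
    subgroup_counts: dict[str, int]
    orf_min: int
    orf_max: int
    orf_mean: int
    pct_group_ii: int


def summarize_family(rows: Sequence) -> FamilySummary:
    """Summary statistics over family-table rows.

    Zinc-type counts use "protein carries at least one finger of residue
    Z" semantics, so a multi-domain protein with both an H-type and a
    variant finger is counted under both labels (matching how overlapping
    type sets are tallied in the family literature).
    """
    if not rows:
        raise ValueError("empty family table")
    from .family_id import parse_pattern_label

    n_two = sum(1 for r in rows if r.n_domains >= 2)
    zinc_counts: dict[str, int] = {}
    for r in rows:
        zs = {parse_pattern_label(lab)[2] for lab in r.zinc_labels}
        for z in sorted(zs):
            key = f"C-C-H-{z}"
            zinc_counts[key] = zinc_counts.get(key, 0) + 1
    group_counts: dict[str, int] = {}
    subgroup_counts: dict[str, int] = {}
    for r in rows:
        group_counts[r.major_group] = group_counts.get(r.major_group, 0) + 1
        if r.group.startswith("II") and r.group != "III":
            subgroup_counts[r.group] = subgroup_counts.get(r.group, 0) + 1
    orfs = [r.orf_aa for r in rows]
    n = len(rows)
    return FamilySummary(
        n_total=n,
        n_two_domain=n_two,
        zinc_type_counts=zinc_counts,
        group_counts=group_counts,
        subgroup_counts=subgroup_counts,
        orf_min=min(orfs),
        orf_max=max(orfs),
        orf_mean=round(sum(orfs) / n),
        pct_group_ii=round(100.0 * group_counts.get("II", 0) / n),
    )
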