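"""Phylogenetic typing of methanol-dehydrogenase-like reads.

Bacteria carry two methanol dehydrogenase large-subunit gene types —
lanthanide-dependent *xoxF* and calcium-dependent *mxaF* — too similar for
simple homology screens to separate.  Each query fragment is therefore
placed, one at a time, on a neighbor-joining tree together with aligned
reference sequences of both types plus an outgroup, and typed by clade
membership after rooting on the outgroup:

* smallest clade containing the query and at least one typed reference is
  pure *xoxF* -> xoxF; pure *mxaF* -> mxaF;
* mixed clade, or a query falling inside / sister to the outgroup ->
  undetermined (the common outcome for short, divergent fragments).

Distances are uncorrected p-distances with pairwise deletion of gapped
columns; a Poisson correction is available behind a flag.  Neighbor joining
follows the Saitou-Nei Q-criterion with deterministic lexicographic
tie-breaking and negative branch-length estimates clamped to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np

from .formats import PhyloTree, TreeNode

__all__ = [
    "Role",
    "AlignedSeqSet",
    "DistanceMatrix",
    "MDHType",
    "MDHTypeCall",
    "p_distance",
    "nj_tree",
    "type_query",
    "type_all",
]

_GAP_CHARS = {"-", "."}


class Role(str, Enum):
    QUERY = "query"
    REF_XOXF = "ref_xoxF"
    REF_MXAF = "ref_mxaF"
    OUTGROUP = "outgroup"


class MDHType(str, Enum):
    XOXF = "xoxF"
    MXAF = "mxaF"
    UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class MDHTypeCall:
    query: str
    call: MDHType


@dataclass
class AlignedSeqSet:
    """Equal-length aligned amino-acid sequences with a role per label."""

    labels: list[str]
    sequences: list[str]
    roles: dict[str, Role]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.sequences):
            raise ValueError("labels and sequences differ in count")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"aligned sequences have unequal lengths: {sorted(lengths)}")
        for label in self.labels:
            if label not in self.roles:
                raise ValueError(f"label {label!r} has no role")


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("distance matrix has nonzero diagonal")
        if np.any(m < 0):
            raise ValueError("distance matrix has negative entries")
        self.matrix = m


def p_distance(seqs: AlignedSeqSet, poisson_correct: bool = False) -> DistanceMatrix:
    """Pairwise distances with pairwise deletion of gapped columns.

    p = mismatches / compared columns, in [0, 1].  With
    ``poisson_correct=True``, d = -ln(1 - p) is returned instead.
    A pair with no comparable columns is an error naming the pair.
    """
    n = len(seqs.labels)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = seqs.sequences[i], seqs.sequences[j]
            compared = mismatch = 0
            for ca, cb in zip(a, b):
                if ca in _GAP_CHARS or cb in _GAP_CHARS:
                    continue
                compared += 1
                if ca != cb:
                    mismatch += 1
            if compared == 0:
                raise ValueError(
                    f"no comparable columns between {seqs.labels[i]!r} and "
                    f"{seqs.labels[j]!r}"
                )
            p = mismatch / compared
            if poisson_correct:
                if p >= 1.0:
                    raise ValueError(
                        f"Poisson correction undefined at p=1 for pair "
                        f"{seqs.labels[i]!r}, {seqs.labels[j]!r}"
                    )
                p = -math.log(1.0 - p)
            m[i, j] = m[j, i] = p
    return DistanceMatrix(labels=list(seqs.labels), matrix=m)


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining.

    Iteratively joins the pair minimizing
    Q(i,j) = (n-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k); branch lengths by
    the standard formulas, negative estimates clamped to zero.  Ties on Q
    break on the lexicographically smallest pair of subtree labels, so the
    result is independent of input order.  The returned tree is unrooted,
    stored with a trifurcating root.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(label=l) for l in dm.labels]
    # tie-break key: lexicographically smallest leaf label beneath the node
    keys: list[str] = list(dm.labels)
    D = dm.matrix.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best_pair: tuple[int, int] | None = None
        best_q = math.inf
        best_key: tuple[str, str] | None = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - r[i] - r[j]
                ki, kj = keys[i], keys[j]
                key = (ki, kj) if ki <= kj else (kj, ki)
                tol = 1e-12 if math.isinf(best_q) else 1e-12 * (1.0 + abs(best_q))
                if q < best_q - tol or (
                    abs(q - best_q) <= tol and (best_key is None or key < best_key)
                ):
                    best_q = q
                    best_pair = (i, j)
                    best_key = key
        i, j = best_pair  # type: ignore[misc]
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        nodes[i].length = li
        nodes[j].length = lj
        new_node = TreeNode(children=[nodes[i], nodes[j]])
        # distances from the new node to the remaining taxa
        new_row = np.zeros(D.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, : len(new_row) - 1] = new_row[:-1]
        D[: len(new_row) - 1, -1] = new_row[:-1]
        nodes.append(new_node)
        keys.append(min(keys[i], keys[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    # final trifurcation: three-point formulas
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        nodes[idx].length = max(ln, 0.0)
    # deterministic child order by subtree key
    children = sorted((nodes[a], nodes[b], nodes[c]), key=lambda nd: min(l.label or "" for l in nd.leaves()))
    root = TreeNode(children=children)
    return PhyloTree(root=root)


# ---------------------------------------------------------------------------
# Clade-rule typing


def _adjacency(tree: PhyloTree) -> tuple[dict[int, list[tuple[int, float]]], dict[int, str]]:
    """Undirected adjacency over node ids; leaf labels by id."""
    adj: dict[int, list[tuple[int, float]]] = {}
    labels: dict[int, str] = {}

    def visit(node: TreeNode) -> None:
        adj.setdefault(id(node), [])
        if node.is_leaf:
            labels[id(node)] = node.label or ""
        for child in node.children:
            adj.setdefault(id(child), [])
            adj[id(node)].append((id(child), child.length))
            adj[id(child)].append((id(node), child.length))
            visit(child)

    visit(tree.root)
    return adj, labels


def _leafset_below(
    adj: Mapping[int, list[tuple[int, float]]],
    labels: Mapping[int, str],
    child: int,
    parent: int,
) -> set[str]:
    """Leaves on the *child* side of the edge (parent, child)."""
    out: set[str] = set()
    stack = [(child, parent)]
    while stack:
        node, prev = stack.pop()
        if node in labels:
            out.add(labels[node])
        for nbr, _ in adj[node]:
            if nbr != prev:
                stack.append((nbr, node))
    return out


def type_query(tree: PhyloTree, roles: Mapping[str, Role]) -> MDHTypeCall:
    """Type the single query leaf of *tree* by rooted clade membership.

    The tree is rooted on the edge subtending the outgroup (the edge
    separating exactly the outgroup leaves if one exists, else the pendant
    edge of the lexicographically smallest outgroup leaf).  Walking rootward
    from the query, the first clade containing a typed reference decides the
    call; a mixed clade, or a query on the outgroup side of the root, is
    undetermined.
    """
    leaf_labels = tree.leaf_labels()
    queries = [l for l in leaf_labels if roles.get(l) is Role.QUERY]
    outgroups = [l for l in leaf_labels if roles.get(l) is Role.OUTGROUP]
    if len(queries) != 1:
        raise ValueError(f"expected exactly one query leaf, got {queries}")
    if not outgroups:
        raise ValueError("no outgroup leaf; cannot root the tree")
    query = queries[0]
    adj, labels = _adjacency(tree)
    og_set = set(outgroups)

    # candidate rooting edge: one whose removal isolates exactly the outgroups
    root_edge: tuple[int, int] | None = None
    for node, nbrs in adj.items():
        for nbr, _ in nbrs:
            if _leafset_below(adj, labels, node, nbr) == og_set:
                root_edge = (nbr, node)  # ingroup side, outgroup side
                break
        if root_edge:
            break
    if root_edge is None:
        smallest = min(outgroups)
        leaf_id = next(i for i, l in labels.items() if l == smallest)
        parent = adj[leaf_id][0][0]
        root_edge = (parent, leaf_id)

    ingroup_anchor, outgroup_anchor = root_edge
    outgroup_side = _leafset_below(adj, labels, outgroup_anchor, ingroup_anchor)
    if query in outgroup_side:
        return MDHTypeCall(query=query, call=MDHType.UNDETERMINED)

    # walk rootward from the query within the ingroup side
    query_id = next(i for i, l in labels.items() if l == query)
    # parents along the path: BFS from ingroup_anchor treating outgroup_anchor as cut
    parent_of: dict[int, int] = {ingroup_anchor: -1}
    stack = [ingroup_anchor]
    while stack:
        node = stack.pop()
        for nbr, _ in adj[node]:
            if nbr == outgroup_anchor and node == ingroup_anchor:
                continue
            if nbr not in parent_of:
                parent_of[nbr] = node
                stack.append(nbr)

    node = parent_of[query_id]
    while node != -1:
        parent = parent_of[node]
        clade = _leafset_below(adj, labels, node, parent if parent != -1 else outgroup_anchor)
        types = {
            roles[l]
            for l in clade
            if roles.get(l) in (Role.REF_XOXF, Role.REF_MXAF)
        }
        if types:
            if types == {Role.REF_XOXF}:
                return MDHTypeCall(query=query, call=MDHType.XOXF)
            if types == {Role.REF_MXAF}:
                return MDHTypeCall(query=query, call=MDHType.MXAF)
            return MDHTypeCall(query=query, call=MDHType.UNDETERMINED)
        node = parent
    return MDHTypeCall(query=query, call=MDHType.UNDETERMINED)


def type_all_with_trees(
    queries: Mapping[str, str],
    refs: Mapping[str, tuple[str, Role]],
    outgroups: Mapping[str, str],
    poisson_correct: bool = False,
) -> tuple[list[MDHTypeCall], dict[str, PhyloTree]]:
    """Type every query fragment, one tree per query; also return the trees.

    *queries* maps label -> aligned sequence; *refs* maps label ->
    (aligned sequence, Role.REF_XOXF or Role.REF_MXAF); *outgroups* maps
    label -> aligned sequence.  Calls come back in sorted query-label order.
    """
    for label, (_, role) in refs.items():
        if role not in (Role.REF_XOXF, Role.REF_MXAF):
            raise ValueError(f"reference {label!r} has non-reference role {role}")
    calls: list[MDHTypeCall] = []
    trees: dict[str, PhyloTree] = {}
    for qlabel in sorted(queries):
        labels = [qlabel, *sorted(refs), *sorted(outgroups)]
        seqs = [queries[qlabel]] + [refs[l][0] for l in sorted(refs)] + [
            outgroups[l] for l in sorted(outgroups)
        ]
        roles: dict[str, Role] = {qlabel: Role.QUERY}
        roles.update({l: refs[l][1] for l in refs})
        roles.update({l: Role.OUTGROUP for l in outgroups})
        aligned = AlignedSeqSet(labels=labels, sequences=seqs, roles=roles)
        dm = p_distance(aligned, poisson_correct=poisson_correct)
        tree = nj_tree(dm)
        trees[qlabel] = tree
        calls.append(type_query(tree, roles))
    return calls, trees


def type_all(
    queries: Mapping[str, str],
    refs: Mapping[str, tuple[str, Role]],
    outgroups: Mapping[str, str],
    poisson_correct: bool = False,
) -> list[MDHTypeCall]:
    """Type every query fragment, one tree per query (see
    :func:`type_all_with_trees`)."""
    calls, _ = type_all_with_trees(queries, refs, outgroups, poisson_correct)
    return calls


def summarize_calls(calls: Sequence[MDHTypeCall]) -> dict[str, int]:
    out = {t.value: 0 for t in MDHType}
    for c in calls:
        out[c.call.value] += 1
    return out
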