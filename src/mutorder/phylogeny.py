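"""Rooted bifurcating cell phylogenies: newick I/O, clade indexing, subtree projection.

The tree is immutable once built.  Nodes are integers in preorder with the
root at 0; every non-root node ``w`` owns the branch from its parent, and
branches are numbered 0..2J-3 in preorder of their child node so that branch
ids are stable and reproducible across runs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "CladeIndex",
    "SubtreeProjection",
    "PhylogenyError",
    "read_newick",
    "write_newick",
    "clade_index",
    "project_subtree",
    "branch_table",
]


class PhylogenyError(ValueError):
    """Raised for malformed trees (polytomies, duplicate tips, bad newick)."""


@dataclass(frozen=True)
class Phylogeny:
    """A rooted bifurcating tree with branch lengths.

    Attributes
    ----------
    parent : np.ndarray
        ``parent[w]`` is the parent node of ``w`` (-1 for the root).
    children : tuple[tuple[int, ...], ...]
        Children of each node, in preorder construction order.
    branch_of_node : np.ndarray
        ``branch_of_node[w]`` is the id of the branch whose child node is
        ``w`` (-1 for the root, which has no incoming branch).
    branch_child : np.ndarray
        Child node of each branch, indexed by branch id.
    lengths : np.ndarray
        Branch lengths indexed by branch id; all >= 0.
    tip_labels : tuple[str, ...]
        Labels of the tips in preorder.
    tip_node : dict[str, int]
        Label -> node id for tips.
    outgroup : str | None
        Optional designated normal/outgroup tip label.
    """

    parent: np.ndarray
    children: tuple[tuple[int, ...], ...]
    branch_of_node: np.ndarray
    branch_child: np.ndarray
    lengths: np.ndarray
    tip_labels: tuple[str, ...]
    tip_node: dict[str, int]
    outgroup: str | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_branches(self) -> int:
        return len(self.branch_child)

    @property
    def root(self) -> int:
        return 0

    def is_tip(self, node: int) -> bool:
        return len(self.children[node]) == 0

    def branch_parent_node(self, branch: int) -> int:
        return int(self.parent[self.branch_child[branch]])

    def validate(self) -> None:
        j = self.n_tips
        if j < 2:
            raise PhylogenyError("tree must have at least 2 tips")
        if self.n_branches != 2 * j - 2:
            raise PhylogenyError(
                f"expected {2 * j - 2} branches for {j} tips, got {self.n_branches}"
            )
        for node, kids in enumerate(self.children):
            if kids and len(kids) != 2:
                raise PhylogenyError(f"node {node} has {len(kids)} children")
        if np.any(self.lengths < 0):
            raise PhylogenyError("negative branch length")
        if len(set(self.tip_labels)) != j:
            raise PhylogenyError("duplicate tip labels")


@dataclass(frozen=True)
class CladeIndex:
    """Precomputed clade structure for O(1) ancestor/descendant queries.

    For branch ``x`` with child node ``w``: ``descendant_edges[x]`` is
    E^x(w) (branches strictly inside the clade below w, excluding x itself),
    ``descendant_tips[x]`` is C^x(w) as tip node ids, ``clade_nodes[x]`` is
    U^x(w).  ``tip_mask[x]`` is a boolean row over the tip ordering.
    """

    tree: Phylogeny
    descendant_edges: tuple[frozenset[int], ...]
    descendant_tips: tuple[frozenset[int], ...]
    clade_nodes: tuple[frozenset[int], ...]
    tip_mask: np.ndarray  # (n_branches, n_tips) bool
    _desc_matrix: np.ndarray = field(repr=False, default=None)

    def is_earlier(self, a: int, b: int) -> bool:
        """True iff branch ``a`` is a strict ancestor branch of branch ``b``."""
        return bool(self._desc_matrix[a, b])

    def are_adjacent(self, a: int, b: int) -> bool:
        """True iff one branch is the immediate parent branch of the other."""
        tree = self.tree
        ca, cb = int(tree.branch_child[a]), int(tree.branch_child[b])
        return tree.parent[cb] == ca or tree.parent[ca] == cb

    @property
    def earlier_matrix(self) -> np.ndarray:
        """Boolean matrix M with M[a, b] = branch a strictly earlier than b."""
        return self._desc_matrix


@dataclass(frozen=True)
class SubtreeProjection:
    """Projection of a tree onto a subset of tips after pruning missing cells.

    ``subtree`` is a valid Phylogeny over the kept tips (or ``None`` when
    fewer than 2 tips remain).  ``branch_paths[k]`` lists the original branch
    ids merged into subtree branch ``k``, ordered root-to-tip; their lengths
    sum to the subtree branch length.  Original branches above the projected
    root or inside pruned clades appear in no path.
    """

    kept_tips: tuple[str, ...]
    subtree: Phylogeny | None
    branch_paths: tuple[tuple[int, ...], ...]

    @property
    def is_identity(self) -> bool:
        return self.subtree is not None and all(
            len(p) == 1 for p in self.branch_paths
        )


def _from_dendropy(dtree: dendropy.Tree, outgroup: str | None,
                   default_length: float | None,
                   resolve_polytomies: bool) -> Phylogeny:
    seed = dtree.seed_node
    if resolve_polytomies:
        dtree.resolve_polytomies(limit=2, update_bipartitions=False)
    # collapse a unifurcating seed node chain (newick like "((A,B));")
    while len(seed.child_nodes()) == 1:
        seed = seed.child_nodes()[0]

    parent: list[int] = []
    children: list[list[int]] = []
    branch_of_node: list[int] = []
    branch_child: list[int] = []
    lengths: list[float] = []
    tip_labels: list[str] = []
    tip_node: dict[str, int] = {}

    def add(dnode, parent_id: int) -> int:
        node_id = len(parent)
        parent.append(parent_id)
        children.append([])
        branch_of_node.append(-1)
        if parent_id >= 0:
            children[parent_id].append(node_id)
            bid = len(branch_child)
            branch_of_node[node_id] = bid
            branch_child.append(node_id)
            el = dnode.edge.length
            if el is None:
                if default_length is None:
                    raise PhylogenyError(
                        "branch without length and no default configured"
                    )
                el = default_length
            if el < 0:
                raise PhylogenyError("negative branch length in newick")
            lengths.append(float(el))
        kids = dnode.child_nodes()
        if not kids:
            label = dnode.taxon.label if dnode.taxon else dnode.label
            if label is None:
                raise PhylogenyError("unlabeled tip")
            if label in tip_node:
                raise PhylogenyError(f"duplicate tip label {label!r}")
            tip_node[label] = node_id
            tip_labels.append(label)
        elif len(kids) != 2:
            raise PhylogenyError(
                f"polytomy with {len(kids)} children (pass resolve_polytomies=True)"
            )
        for kid in kids:
            add(kid, node_id)
        return node_id

    add(seed, -1)
    tree = Phylogeny(
        parent=np.asarray(parent, dtype=np.int64),
        children=tuple(tuple(c) for c in children),
        branch_of_node=np.asarray(branch_of_node, dtype=np.int64),
        branch_child=np.asarray(branch_child, dtype=np.int64),
        lengths=np.asarray(lengths, dtype=float),
        tip_labels=tuple(tip_labels),
        tip_node=tip_node,
        outgroup=outgroup,
    )
    tree.validate()
    if outgroup is not None and outgroup not in tree.tip_node:
        raise PhylogenyError(f"outgroup {outgroup!r} is not a tip")
    return tree


def read_newick(text: str, outgroup: str | None = None, *,
                default_length: float | None = None,
                resolve_polytomies: bool = False) -> Phylogeny:
    """Parse a newick string into a :class:`Phylogeny`.

    Branch ids are assigned in deterministic preorder.  Polytomies are
    rejected unless ``resolve_polytomies`` is set, in which case they are
    resolved deterministically with zero-length branches.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise PhylogenyError(f"newick parse failure: {exc}") from exc
    return _from_dendropy(dtree, outgroup, default_length, resolve_polytomies)


def write_newick(tree: Phylogeny, *, branch_labels: dict[int, str] | None = None) -> str:
    """Serialize back to newick, optionally annotating branches with labels."""
    buf = io.StringIO()

    def emit(node: int) -> None:
        kids = tree.children[node]
        if kids:
            buf.write("(")
            for i, kid in enumerate(kids):
                if i:
                    buf.write(",")
                emit(kid)
            buf.write(")")
        else:
            buf.write(_tip_label(tree, node))
        bid = int(tree.branch_of_node[node])
        if bid >= 0:
            if branch_labels and bid in branch_labels:
                buf.write(f"[&{branch_labels[bid]}]")
            buf.write(f":{tree.lengths[bid]:.10g}")

    emit(tree.root)
    buf.write(";")
    return buf.getvalue()


def _tip_label(tree: Phylogeny, node: int) -> str:
    for lab, n in tree.tip_node.items():
        if n == node:
            return lab
    raise KeyError(node)


def clade_index(tree: Phylogeny) -> CladeIndex:
    """Compute E^x(w), C^x(w), U^x(w) for every branch x."""
    nb = tree.n_branches
    nt = tree.n_tips
    tip_order = {tree.tip_node[lab]: k for k, lab in enumerate(tree.tip_labels)}

    desc_edges: list[frozenset[int]] = [frozenset()] * nb
    desc_tips: list[frozenset[int]] = [frozenset()] * nb
    clade_nodes: list[frozenset[int]] = [frozenset()] * nb
    tip_mask = np.zeros((nb, nt), dtype=bool)

    # postorder accumulation
    post = []
    stack = [tree.root]
    while stack:
        node = stack.pop()
        post.append(node)
        stack.extend(tree.children[node])
    for node in reversed(post):
        bid = int(tree.branch_of_node[node])
        if bid < 0:
            continue
        edges: set[int] = set()
        tips: set[int] = set()
        nodes: set[int] = {node}
        if tree.is_tip(node):
            tips.add(node)
        for kid in tree.children[node]:
            kb = int(tree.branch_of_node[kid])
            edges.add(kb)
            edges |= desc_edges[kb]
            tips |= desc_tips[kb]
            nodes |= clade_nodes[kb]
        desc_edges[bid] = frozenset(edges)
        desc_tips[bid] = frozenset(tips)
        clade_nodes[bid] = frozenset(nodes)
        for t in tips:
            tip_mask[bid, tip_order[t]] = True

    desc_matrix = np.zeros((nb, nb), dtype=bool)
    for x in range(nb):
        for y in desc_edges[x]:
            desc_matrix[x, y] = True

    return CladeIndex(
        tree=tree,
        descendant_edges=tuple(desc_edges),
        descendant_tips=tuple(desc_tips),
        clade_nodes=tuple(clade_nodes),
        tip_mask=tip_mask,
        _desc_matrix=desc_matrix,
    )


def project_subtree(tree: Phylogeny, missing_tips: set[str]) -> SubtreeProjection:
    """Prune ``missing_tips`` and suppress degree-2 nodes, merging path lengths.

    Raises :class:`PhylogenyError` if fewer than 2 tips remain.
    """
    unknown = missing_tips - set(tree.tip_labels)
    if unknown:
        raise PhylogenyError(f"missing_tips not in tree: {sorted(unknown)}")
    kept = [lab for lab in tree.tip_labels if lab not in missing_tips]
    if len(kept) < 2:
        raise PhylogenyError("fewer than 2 tips remain after pruning")
    if not missing_tips:
        paths = tuple((b,) for b in range(tree.n_branches))
        return SubtreeProjection(tuple(kept), tree, paths)

    keep_node = np.zeros(tree.n_nodes, dtype=bool)
    for lab in kept:
        node = tree.tip_node[lab]
        while node >= 0 and not keep_node[node]:
            keep_node[node] = True
            node = int(tree.parent[node])

    # find projected root: descend while a kept node has a single kept child
    def kept_children(node: int) -> list[int]:
        return [k for k in tree.children[node] if keep_node[k]]

    new_root = tree.root
    while len(kept_children(new_root)) == 1:
        new_root = kept_children(new_root)[0]

    parent: list[int] = []
    children: list[list[int]] = []
    branch_of_node: list[int] = []
    branch_child: list[int] = []
    lengths: list[float] = []
    tip_labels: list[str] = []
    tip_node: dict[str, int] = {}
    branch_paths: list[tuple[int, ...]] = []

    def build(orig: int, parent_id: int, path: list[int]) -> None:
        kids = kept_children(orig)
        if len(kids) == 1 and parent_id >= 0:
            kid = kids[0]
            build(kid, parent_id, path + [int(tree.branch_of_node[kid])])
            return
        node_id = len(parent)
        parent.append(parent_id)
        children.append([])
        branch_of_node.append(-1)
        if parent_id >= 0:
            children[parent_id].append(node_id)
            bid = len(branch_child)
            branch_of_node[node_id] = bid
            branch_child.append(node_id)
            lengths.append(float(sum(tree.lengths[b] for b in path)))
            branch_paths.append(tuple(path))
        if not kids:
            lab = _tip_label(tree, orig)
            tip_node[lab] = node_id
            tip_labels.append(lab)
        for kid in kids:
            build(kid, node_id, [int(tree.branch_of_node[kid])])

    build(new_root, -1, [])
    sub = Phylogeny(
        parent=np.asarray(parent, dtype=np.int64),
        children=tuple(tuple(c) for c in children),
        branch_of_node=np.asarray(branch_of_node, dtype=np.int64),
        branch_child=np.asarray(branch_child, dtype=np.int64),
        lengths=np.asarray(lengths, dtype=float),
        tip_labels=tuple(tip_labels),
        tip_node=tip_node,
        outgroup=tree.outgroup if tree.outgroup in tip_node else None,
    )
    sub.validate()
    return SubtreeProjection(tuple(kept), sub, tuple(branch_paths))


def branch_table(tree: Phylogeny, index: CladeIndex | None = None) -> "pd.DataFrame":
    """Branch summary: id, parent node, child node, length, descendant tips."""
    import pandas as pd

    index = index or clade_index(tree)
    rows = []
    for b in range(tree.n_branches):
        child = int(tree.branch_child[b])
        tips = sorted(
            _tip_label(tree, t) for t in index.descendant_tips[b]
        )
        rows.append({
            "branch_id": b,
            "parent": int(tree.parent[child]),
            "child": child,
            "length": float(tree.lengths[b]),
            "descendant_tips": ",".join(tips),
        })
    return pd.DataFrame(rows)
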