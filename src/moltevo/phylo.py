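"""Rooted phylogenies: Newick IO, pruning, and phylogenetic correlation.

Trees are held as :class:`dendropy.Tree` objects; this module adds the
validation and transformations the comparative analyses need — multi-tree
set handling over a shared taxon set, pruning to a species subset with
exact path-length preservation, an array "flattening" used by the
likelihood engine, and the scaled phylogenetic correlation matrix that
enters the mixed model as the covariance of the species-level random
effect.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "PhyloError",
    "TreeSet",
    "parse_newick_set",
    "parse_newick",
    "write_newick",
    "prune_to_taxa",
    "tip_labels",
    "tree_depths",
    "check_ultrametric",
    "phylo_correlation",
    "FlatTree",
    "flatten_tree",
]


class PhyloError(ValueError):
    pass


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def parse_newick(text: str) -> dendropy.Tree:
    """Parse a single rooted Newick statement, validating branch lengths."""
    trees = parse_newick_set(text)
    if len(trees) != 1:
        raise PhyloError(f"expected one tree, found {len(trees)}")
    return trees[0]


@dataclass
class TreeSet:
    """Ordered collection of rooted trees over an identical taxon set."""

    trees: list[dendropy.Tree]
    provenance: str = ""

    def __post_init__(self):
        if not self.trees:
            raise PhyloError("empty tree set")
        ref = set(tip_labels(self.trees[0]))
        for i, t in enumerate(self.trees[1:], start=2):
            tips = set(tip_labels(t))
            if tips != ref:
                only_ref = sorted(ref - tips)[:5]
                only_t = sorted(tips - ref)[:5]
                raise PhyloError(
                    f"tree {i} has a different tip set (e.g. missing {only_ref}, "
                    f"extra {only_t})"
                )

    def __len__(self) -> int:
        return len(self.trees)

    def __getitem__(self, i):
        return self.trees[i]

    def __iter__(self):
        return iter(self.trees)

    @property
    def taxa(self) -> list[str]:
        return sorted(tip_labels(self.trees[0]))


def _validate_tree(tree: dendropy.Tree, line: int) -> None:
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            edge.length = 0.0
        if not np.isfinite(edge.length) or edge.length < 0:
            raise PhyloError(f"tree {line}: negative or non-finite branch length")
    if len(tree.leaf_nodes()) < 2:
        raise PhyloError(f"tree {line}: fewer than two tips")
    # collapse zero-length internal branches into polytomies
    to_collapse = [
        e
        for e in tree.preorder_edge_iter()
        if e.length == 0.0
        and e.head_node is not tree.seed_node
        and not e.head_node.is_leaf()
    ]
    for e in to_collapse:
        e.collapse()


def parse_newick_set(source, provenance: str = "") -> TreeSet:
    """Read one or more ';'-terminated Newick statements into a TreeSet.

    Accepts a string, an open text stream, or a path.  Trees appear in file
    order; tip sets must be identical across trees.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
        if "(" not in text:  # looks like a path
            with open(text) as fh:
                text = fh.read()
    statements = [s.strip() for s in text.split(";") if s.strip()]
    if not statements:
        raise PhyloError("no Newick statements found")
    trees = []
    for i, stmt in enumerate(statements, start=1):
        if stmt.count("(") != stmt.count(")"):
            raise PhyloError(f"tree {i}: unbalanced parentheses")
        try:
            tree = dendropy.Tree.get(
                data=stmt + ";",
                schema="newick",
                rooting="force-rooted",
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise PhyloError(f"tree {i}: parse error: {exc}") from exc
        _validate_tree(tree, i)
        trees.append(tree)
    if text.rstrip() and not text.rstrip().endswith(";"):
        raise PhyloError(f"tree {len(statements)}: missing terminating ';'")
    return TreeSet(trees, provenance=provenance)


def write_newick(trees, path=None) -> str:
    """Serialize a tree or TreeSet to plain Newick with branch lengths."""
    if isinstance(trees, dendropy.Tree):
        trees = [trees]
    out = io.StringIO()
    for t in trees:
        out.write(
            t.as_string(
                schema="newick",
                suppress_rooting=True,
                unquoted_underscores=True,
                real_value_format_specifier=".10g",
            ).strip()
        )
        out.write("\n")
    text = out.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def prune_to_taxa(tree: dendropy.Tree, taxa) -> dendropy.Tree:
    """Induced subtree on ``taxa``; tip-to-tip path lengths are preserved."""
    taxa = set(taxa)
    present = set(tip_labels(tree))
    unknown = sorted(taxa - present)
    if unknown:
        raise PhyloError(f"taxa not in tree: {unknown}")
    if len(taxa) < 2:
        raise PhyloError("need at least two taxa to prune to")
    pruned = tree.clone(depth=1)
    keep = [t for t in pruned.taxon_namespace if t.label in taxa]
    pruned.retain_taxa(keep)
    # retain_taxa suppresses unifurcations, summing branch lengths; drop any
    # residual root unifurcation as well
    if len(pruned.seed_node.child_nodes()) == 1:
        child = pruned.seed_node.child_nodes()[0]
        child.edge.length = None
        pruned.seed_node = child
        child.parent_node = None
    return pruned


def tree_depths(tree: dendropy.Tree) -> dict:
    """Root-to-tip distance for every tip label."""
    depths = {}
    dist = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            dist[node] = dist[node.parent_node] + (node.edge.length or 0.0)
        if node.is_leaf():
            depths[node.taxon.label] = dist[node]
    return depths


def check_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-3) -> float:
    """Verify equal root-to-tip depths within ``rel_tol``; return mean depth.

    Dated supertrees are ultrametric in principle, but text truncation of
    branch lengths introduces jitter, so a relative spread up to ``rel_tol``
    is accepted and depths are averaged.
    """
    depths = tree_depths(tree)
    vals = np.array(list(depths.values()))
    mean = float(vals.mean())
    if mean <= 0:
        raise PhyloError("tree has zero depth")
    spread = (vals.max() - vals.min()) / mean
    if spread > rel_tol:
        worst = max(depths, key=lambda k: abs(depths[k] - mean))
        raise PhyloError(
            f"tree is not ultrametric (relative depth spread {spread:.3g}); "
            f"worst tip: {worst}"
        )
    return mean


def phylo_correlation(tree: dendropy.Tree, taxa=None, rel_tol: float = 1e-3):
    """Phylogenetic correlation matrix: shared path length / tree depth.

    Entry (i, j) is the root-to-MRCA distance of tips i and j divided by
    the (mean) tree depth; the diagonal is 1 for ultrametric trees.  The
    result is the standardized covariance of a Brownian trait on the tree
    and is positive semi-definite by construction (verified numerically).

    Returns ``(labels, matrix)`` with rows ordered by ``taxa`` if given,
    else by sorted tip label.
    """
    depth = check_ultrametric(tree, rel_tol=rel_tol)
    labels = sorted(tip_labels(tree)) if taxa is None else list(taxa)
    index = {lab: i for i, lab in enumerate(labels)}
    missing = set(index) - set(tip_labels(tree))
    if missing:
        raise PhyloError(f"taxa not in tree: {sorted(missing)}")
    n = len(labels)
    C = np.zeros((n, n))
    node_depth = {tree.seed_node: 0.0}
    # postorder: tips below each node; tips in different child subtrees have
    # their MRCA at this node
    below: dict = {}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            node_depth[node] = node_depth[node.parent_node] + (node.edge.length or 0.0)
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            lab = node.taxon.label
            below[node] = [index[lab]] if lab in index else []
            if lab in index:
                C[index[lab], index[lab]] = node_depth[node] / depth
            continue
        kids = [below[c] for c in node.child_nodes()]
        h = node_depth[node] / depth
        for a in range(len(kids)):
            for b in range(a + 1, len(kids)):
                for i in kids[a]:
                    C[i, kids[b]] = h
                    C[kids[b], i] = h
        below[node] = [i for k in kids for i in k]
    eigmin = float(np.linalg.eigvalsh(C).min())
    if eigmin < -1e-8:
        raise PhyloError(f"correlation matrix not PSD (min eigenvalue {eigmin:.3g})")
    return labels, C


# ---------------------------------------------------------------------------
# array representation for the likelihood engine


@dataclass
class FlatTree:
    """Tree flattened to arrays for fast postorder likelihood evaluation.

    Nodes are indexed 0..n_nodes-1 with tips first (in ``tip_labels``
    order); ``postorder`` lists internal nodes children-before-parents;
    ``branch_lengths[i]`` is the branch above node i (root entry unused).
    """

    tip_labels: list[str]
    n_nodes: int
    root: int
    postorder: np.ndarray  # internal node ids, children-first
    child_ptr: np.ndarray  # CSR offsets into child_idx, per internal node
    child_idx: np.ndarray
    branch_lengths: np.ndarray

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)


def flatten_tree(tree: dendropy.Tree) -> FlatTree:
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    ids = {node: i for i, node in enumerate(leaves)}
    internal = [n for n in tree.postorder_node_iter() if not n.is_leaf()]
    for node in internal:
        ids[node] = len(ids)
    n_nodes = len(ids)
    blen = np.zeros(n_nodes)
    for node, i in ids.items():
        if node is not tree.seed_node:
            blen[i] = node.edge.length or 0.0
    postorder = np.array([ids[n] for n in internal], dtype=np.int64)
    ptr = [0]
    idx = []
    for node in internal:
        idx.extend(ids[c] for c in node.child_nodes())
        ptr.append(len(idx))
    return FlatTree(
        tip_labels=labels,
        n_nodes=n_nodes,
        root=ids[tree.seed_node],
        postorder=postorder,
        child_ptr=np.array(ptr, dtype=np.int64),
        child_idx=np.array(idx, dtype=np.int64),
        branch_lengths=blen,
    )
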