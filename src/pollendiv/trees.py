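"""Reading, validating and indexing time-calibrated phylogenies.

Trees are strictly rooted, binary, with finite non-negative branch lengths in
absolute time (Myr, no unit conversion is attempted).  Parsing of Newick and
NEXUS (TREES block, translate tables, quoted labels) is delegated to dendropy;
everything downstream works on a flat array representation: tips are node
indices ``0 .. n_tips-1``, internal nodes ``n_tips .. 2*n_tips-2``, and
``postorder`` lists the internal nodes children-first, ending at the root.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import (
    DegenerateTreeError,
    TreeParseError,
    TreeValidationError,
    UnsupportedTopologyError,
)

__all__ = [
    "Phylogeny",
    "UltrametricReport",
    "read_tree",
    "read_tree_file",
    "write_newick",
    "validate_ultrametric",
]

#: Default relative tolerance for ultrametricity; BEAST/chronogram output is
#: typically rounded so that stricter tolerances reject valid published trees.
DEFAULT_ULTRAMETRIC_RTOL = 1e-4


@dataclass(frozen=True)
class Phylogeny:
    """Rooted binary ultrametric-capable tree in flat-array form.

    Attributes
    ----------
    tip_labels
        Unique tip names; tip ``i`` carries ``tip_labels[i]``.
    parent
        Parent index per node; ``-1`` at the root.
    left, right
        Child indices per node; ``-1`` at tips.
    blen
        Length of the branch subtending each node; 0.0 at the root.
    postorder
        Internal node indices, children-before-parents (root last).
    """

    tip_labels: tuple[str, ...]
    parent: np.ndarray
    left: np.ndarray
    right: np.ndarray
    blen: np.ndarray
    postorder: np.ndarray = field(repr=False)

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(self.postorder[-1])

    def depths(self) -> np.ndarray:
        """Root-to-node path lengths for every node (preorder accumulation)."""
        d = np.zeros(self.n_nodes)
        for node in self.postorder[::-1]:
            for child in (self.left[node], self.right[node]):
                d[child] = d[node] + self.blen[child]
        return d

    def node_ages(self) -> np.ndarray:
        """Age of each node measured from the most recent tip (max depth)."""
        d = self.depths()
        return d.max() - d

    @property
    def height(self) -> float:
        return float(self.depths()[: self.n_tips].max())

    @property
    def total_branch_length(self) -> float:
        return float(self.blen.sum())

    def children(self, node: int) -> tuple[int, int]:
        return int(self.left[node]), int(self.right[node])

    def is_tip(self, node: int) -> bool:
        return node < self.n_tips

    def tip_index(self, label: str) -> int:
        try:
            return self.tip_labels.index(label)
        except ValueError:
            raise KeyError(f"tip label {label!r} not in tree") from None

    # ------------------------------------------------------------------
    # conversion
    # ------------------------------------------------------------------
    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "Phylogeny":
        return _from_dendropy(dtree)

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        dtree = dendropy.Tree(taxon_namespace=taxa)
        nodes = {}
        for i, label in enumerate(self.tip_labels):
            nd = dendropy.Node()
            nd.taxon = taxa.new_taxon(label)
            nd.edge.length = float(self.blen[i])
            nodes[i] = nd
        for node in self.postorder:
            nd = dendropy.Node()
            nd.edge.length = float(self.blen[node])
            nd.add_child(nodes[self.left[node]])
            nd.add_child(nodes[self.right[node]])
            nodes[int(node)] = nd
        dtree.seed_node = nodes[self.root]
        dtree.is_rooted = True
        return dtree

    def newick(self) -> str:
        """Newick string with branch lengths at 10 significant digits."""

        def rec(node: int) -> str:
            if self.is_tip(node):
                core = _quote_label(self.tip_labels[node])
            else:
                core = f"({rec(int(self.left[node]))},{rec(int(self.right[node]))})"
            if node == self.root:
                return core
            return f"{core}:{self.blen[node]:.10g}"

        return rec(self.root) + ";"


def _quote_label(label: str) -> str:
    if any(c in label for c in " ()[]{}:;,'\""):
        return "'" + label.replace("'", "''") + "'"
    return label


def _from_dendropy(dtree: dendropy.Tree) -> Phylogeny:
    seed = dtree.seed_node
    if seed is None:
        raise TreeValidationError("empty tree")
    # collapse a unifurcating root edge is NOT attempted: reject instead
    dnodes = list(dtree.preorder_node_iter())
    tips = [nd for nd in dnodes if nd.is_leaf()]
    internals = [nd for nd in dnodes if not nd.is_leaf()]
    if len(tips) < 2:
        raise TreeValidationError("tree must have at least two tips")
    for nd in internals:
        k = len(nd.child_nodes())
        if k != 2:
            raise UnsupportedTopologyError(
                f"internal node with {k} children; only strictly binary "
                "rooted trees are supported"
            )
    labels = []
    for nd in tips:
        label = nd.taxon.label if nd.taxon is not None else nd.label
        if label is None or label == "":
            raise TreeValidationError("tip without a label")
        labels.append(str(label))
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise TreeValidationError(f"duplicate tip labels: {dupes}")

    n_tips = len(tips)
    n_nodes = 2 * n_tips - 1
    index = {}
    for i, nd in enumerate(tips):
        index[id(nd)] = i
    # postorder over internals so children are always indexed first
    post_internals = [nd for nd in dtree.postorder_node_iter() if not nd.is_leaf()]
    for j, nd in enumerate(post_internals):
        index[id(nd)] = n_tips + j

    parent = np.full(n_nodes, -1, dtype=np.int64)
    left = np.full(n_nodes, -1, dtype=np.int64)
    right = np.full(n_nodes, -1, dtype=np.int64)
    blen = np.zeros(n_nodes)
    for nd in dnodes:
        i = index[id(nd)]
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            if nd.edge.length is None:
                raise TreeValidationError(
                    f"branch without a length above node {i}"
                )
            length = float(nd.edge.length)
            if not np.isfinite(length) or length < 0:
                raise TreeValidationError(
                    f"non-finite or negative branch length {length} above node {i}"
                )
            blen[i] = length
        if not nd.is_leaf():
            c0, c1 = nd.child_nodes()
            left[i] = index[id(c0)]
            right[i] = index[id(c1)]
    postorder = np.array([index[id(nd)] for nd in post_internals], dtype=np.int64)
    tree = Phylogeny(
        tip_labels=tuple(labels),
        parent=parent,
        left=left,
        right=right,
        blen=blen,
        postorder=postorder,
    )
    assert len(postorder) == n_tips - 1  # binary rooted: n-1 internals
    return tree


def read_tree(text: str) -> Phylogeny:
    """Parse a single tree from a Newick or NEXUS string.

    The schema is auto-detected (``#NEXUS`` header).  Polytomies, duplicate
    tip labels and missing/negative branch lengths are rejected.
    """
    stripped = text.lstrip()
    schema = "nexus" if stripped[:6].upper() == "#NEXUS" else "newick"
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema=schema,
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except (dendropy.utility.error.DataParseError, ValueError) as exc:
        raise TreeParseError(f"could not parse {schema} input: {exc}") from exc
    return _from_dendropy(dtree)


def read_tree_file(path) -> Phylogeny:
    with open(path) as fh:
        return read_tree(fh.read())


def write_newick(tree: Phylogeny, path=None) -> str:
    """Serialize to Newick; round-trips topology and branch lengths."""
    text = tree.newick() + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


@dataclass(frozen=True)
class UltrametricReport:
    passed: bool
    max_relative_deviation: float
    mean_depth: float
    offending_tips: tuple[str, ...]


def validate_ultrametric(
    tree: Phylogeny, rel_tol: float = DEFAULT_ULTRAMETRIC_RTOL
) -> UltrametricReport:
    """Check that all root-to-tip path lengths agree to ``rel_tol``.

    The deviation measure is ``|depth(tip) - mean depth| / mean depth``; the
    report lists tips exceeding the tolerance.
    """
    depths = tree.depths()[: tree.n_tips]
    mean = float(depths.mean())
    if mean <= 0:
        raise DegenerateTreeError("tree has zero depth")
    rel = np.abs(depths - mean) / mean
    bad = rel > rel_tol
    return UltrametricReport(
        passed=not bool(bad.any()),
        max_relative_deviation=float(rel.max()),
        mean_depth=mean,
        offending_tips=tuple(np.asarray(tree.tip_labels)[bad]),
    )
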