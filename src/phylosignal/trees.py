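"""Tree representation, Newick I/O, monophyly constraints, and exhaustive
enumeration of rooted backbone topologies.

Trees are :class:`dendropy.Tree` objects throughout. A *backbone topology*
is a rooted binary tree whose leaves are clade labels rather than taxa; all
``(2k-3)!!`` rooted shapes on ``k`` labels are generated by recursive leaf
insertion and deduplicated through a canonical sorted-cluster form. Backbones
are expanded into full candidate trees by grafting frozen within-clade
subtrees (neighbor-joining on model-corrected distances) onto the backbone
leaves, with the outgroup attached at the root.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import yaml

__all__ = [
    "TreeFormatError",
    "CladeConstraintSet",
    "parse_newick",
    "write_newick",
    "canonical_newick",
    "leaf_clusters",
    "cluster_distance",
    "enumerate_backbones",
    "is_monophyletic",
    "build_constrained_tree",
    "within_clade_resolution",
    "resolve_group",
    "jc_distance_matrix",
]


class TreeFormatError(ValueError):
    """Raised for malformed Newick input."""


# -- Newick I/O -------------------------------------------------------------

def parse_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a rooted dendropy tree."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise TreeFormatError(f"cannot parse Newick: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise TreeFormatError("duplicate leaf labels in Newick input")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()


def _newick_fragment(tree: dendropy.Tree) -> str:
    """Newick of a tree without the trailing semicolon, for composition."""
    s = write_newick(tree)
    return s.rstrip(";").strip()


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {lf.taxon.label for lf in tree.leaf_node_iter()}


# -- canonical form ---------------------------------------------------------

def _canonical(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    parts = sorted(_canonical(c) for c in node.child_nodes())
    return "(" + ",".join(parts) + ")"


def canonical_newick(tree: dendropy.Tree) -> str:
    """Topology-only canonical Newick (children sorted recursively)."""
    return _canonical(tree.seed_node) + ";"


def leaf_clusters(tree: dendropy.Tree) -> frozenset[frozenset[str]]:
    """The set of leaf-descendant sets over all internal nodes (rooted clusters)."""
    clusters = []
    for node in tree.preorder_node_iter():
        if not node.is_leaf():
            clusters.append(frozenset(lf.taxon.label for lf in node.leaf_iter()))
    return frozenset(clusters)


def cluster_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Symmetric difference of rooted cluster sets (rooted RF distance)."""
    c1, c2 = leaf_clusters(t1), leaf_clusters(t2)
    return len(c1 ^ c2)


# -- backbone enumeration ---------------------------------------------------

def _insertions(shape, leaf):
    """All rooted trees obtained by attaching ``leaf`` to nested-tuple ``shape``."""
    out = [(shape, leaf)]
    if isinstance(shape, tuple):
        left, right = shape
        out.extend((nl, right) for nl in _insertions(left, leaf))
        out.extend((left, nr) for nr in _insertions(right, leaf))
    return out


def _shape_to_newick(shape) -> str:
    if isinstance(shape, tuple):
        parts = sorted(_shape_to_newick(s) for s in shape)
        return "(" + ",".join(parts) + ")"
    return shape


def enumerate_backbones(clade_labels: Sequence[str]) -> list[dendropy.Tree]:
    """All distinct rooted binary topologies on the given labels.

    There are ``(2k-3)!!`` of them for ``k`` labels (15 for k=4). Output
    order is deterministic (sorted canonical Newick); duplicates are ruled
    out by canonical-form hashing.
    """
    labels = list(clade_labels)
    if len(labels) < 2:
        raise ValueError("need at least 2 clade labels")
    if len(set(labels)) != len(labels):
        raise ValueError("clade labels must be unique")
    shapes = [labels[0]]
    for lab in labels[1:]:
        shapes = [s for shape in shapes for s in _insertions(shape, lab)]
    canon = {_shape_to_newick(s) for s in shapes}
    expected = 1
    for i in range(2, len(labels)):
        expected *= 2 * i - 1
    assert len(canon) == expected, "backbone enumeration produced duplicates"
    return [parse_newick(s + ";") for s in sorted(canon)]


# -- monophyly --------------------------------------------------------------

def is_monophyletic(tree: dendropy.Tree, taxon_set) -> bool:
    """True iff some node's leaf-descendant set equals ``taxon_set`` (rooted)."""
    target = frozenset(taxon_set)
    labels = leaf_labels(tree)
    unknown = target - labels
    if unknown:
        raise ValueError(f"taxa not in tree: {sorted(unknown)}")
    if len(target) == 1:
        return True
    for node in tree.preorder_internal_node_iter():
        if frozenset(lf.taxon.label for lf in node.leaf_iter()) == target:
            return True
    return False


# -- constraint sets --------------------------------------------------------

@dataclass(frozen=True)
class CladeConstraintSet:
    """Named monophyly constraints plus an outgroup.

    ``clades`` maps clade label -> taxon set; sets must be pairwise disjoint
    and disjoint from the outgroup.
    """

    clades: dict[str, frozenset[str]]
    outgroup: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(
            self, "clades", {k: frozenset(v) for k, v in self.clades.items()}
        )
        object.__setattr__(self, "outgroup", frozenset(self.outgroup))
        seen: set[str] = set()
        for label, taxa in list(self.clades.items()) + [("outgroup", self.outgroup)]:
            overlap = seen & taxa
            if overlap:
                raise ValueError(f"taxa appear in more than one group: {sorted(overlap)}")
            seen |= taxa

    @property
    def clade_labels(self) -> list[str]:
        return list(self.clades)

    @property
    def all_taxa(self) -> frozenset[str]:
        out = frozenset().union(*self.clades.values())
        return out | self.outgroup

    @classmethod
    def from_yaml(cls, path) -> "CladeConstraintSet":
        data = yaml.safe_load(Path(path).read_text())
        return cls(
            clades={k: frozenset(v) for k, v in data["clades"].items()},
            outgroup=frozenset(data.get("outgroup", [])),
        )

    def to_yaml(self, path) -> None:
        data = {
            "clades": {k: sorted(v) for k, v in self.clades.items()},
            "outgroup": sorted(self.outgroup),
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


# -- constrained tree construction ------------------------------------------

def build_constrained_tree(
    backbone: dendropy.Tree,
    within_clade_subtrees: Mapping[str, dendropy.Tree],
    outgroup_subtree: dendropy.Tree | None = None,
) -> dendropy.Tree:
    """Expand a backbone into a full tree by grafting clade subtrees.

    Each backbone leaf (a clade label) is replaced by the corresponding
    subtree; the outgroup subtree, if given, is attached as sister to the
    whole backbone at the root. Every clade is monophyletic in the result
    and the backbone relationships among clades are preserved.
    """
    backbone_leaves = leaf_labels(backbone)
    missing = backbone_leaves - set(within_clade_subtrees)
    if missing:
        raise ValueError(f"no subtree supplied for clades: {sorted(missing)}")

    def expand(node: dendropy.Node) -> str:
        if node.is_leaf():
            return _newick_fragment(within_clade_subtrees[node.taxon.label])
        return "(" + ",".join(expand(c) for c in node.child_nodes()) + ")"

    core = expand(backbone.seed_node)
    if outgroup_subtree is not None and leaf_labels(outgroup_subtree):
        newick = f"({core},{_newick_fragment(outgroup_subtree)});"
    else:
        newick = core + ";"
    return parse_newick(newick)


# -- within-clade resolution (NJ on JC distances) ---------------------------

_DNA_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_MAX_DISTANCE = 5.0  # saturation cap, substitutions/site


def jc_distance_matrix(alignment, taxa: Sequence[str]) -> np.ndarray:
    """Jukes-Cantor corrected pairwise distances for the given taxa.

    Only columns where both sequences carry an unambiguous nucleotide are
    compared. Saturated or non-overlapping pairs are capped at a large
    finite distance so neighbor joining stays defined.
    """
    sub = alignment.subset_taxa(taxa)
    coded = np.full(sub.matrix.shape, -1, dtype=np.int8)
    for sym, code in _DNA_CODE.items():
        coded[sub.matrix == sym] = code
    n = len(taxa)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (coded[i] >= 0) & (coded[j] >= 0)
            n_ok = int(ok.sum())
            if n_ok == 0:
                d = _MAX_DISTANCE
            else:
                p = float((coded[i, ok] != coded[j, ok]).mean())
                if p >= 0.7499:
                    d = _MAX_DISTANCE
                else:
                    d = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
            dm[i, j] = dm[j, i] = d
    return dm


def resolve_group(alignment, taxa: Sequence[str]) -> dendropy.Tree:
    """Rooted subtree for a taxon group via neighbor joining on JC distances.

    Deterministic: taxa are processed in sorted order and the NJ tree is
    midpoint-rooted (falling back to the smallest taxon's pendant edge when
    all distances vanish).
    """
    taxa = sorted(taxa)
    present = [
        t for t in taxa
        if not alignment.missing_mask()[alignment.taxa.index(t)].all()
    ]
    if not present:
        raise ValueError("group has no taxon with any data")
    if len(taxa) == 1:
        return parse_newick(f"{taxa[0]};")
    if len(taxa) == 2:
        d = jc_distance_matrix(alignment, taxa)[0, 1]
        return parse_newick(f"({taxa[0]}:{d / 2:.6g},{taxa[1]}:{d / 2:.6g});")
    from io import StringIO

    from skbio import DistanceMatrix
    from skbio.tree import nj

    dm = DistanceMatrix(jc_distance_matrix(alignment, taxa), ids=taxa)
    buf = StringIO()
    nj(dm).write(buf)
    tree = parse_newick(buf.getvalue())
    total = 0.0
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
        total += edge.length or 0.0
    if total > 0:
        tree.reroot_at_midpoint(update_bipartitions=False)
    else:
        anchor = next(
            lf for lf in tree.leaf_node_iter() if lf.taxon.label == taxa[0]
        )
        tree.reroot_at_edge(anchor.edge, update_bipartitions=False)
    return parse_newick(write_newick(tree))


def within_clade_resolution(alignment, constraints: CladeConstraintSet) -> dict[str, dendropy.Tree]:
    """Frozen per-clade subtrees, one NJ resolution reused across backbones."""
    return {
        label: resolve_group(alignment, sorted(taxa))
        for label, taxa in constraints.clades.items()
    }
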