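"""Fitch parsimony tree lengths for discrete morphological matrices, plus a
constraint-respecting NNI refinement of grafted starting trees.

Characters are unordered (nonadditive); ``?`` and ``-`` are fully ambiguous
and never force a step. The Fitch pass runs bottom-up over all characters at
once using bitmask state sets. ``constrained_best_length`` mirrors a
constrained parsimony search at desk scale: build the backbone-constrained
starting tree, then accept nearest-neighbor interchanges only when they
shorten the tree and keep every monophyly constraint (and the backbone
arrangement itself) intact.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .trees import (
    CladeConstraintSet,
    build_constrained_tree,
    canonical_newick,
    is_monophyletic,
    leaf_labels,
    parse_newick,
)

MAX_STATES = 10
_FULL_MASK = np.uint16((1 << MAX_STATES) - 1)
_MISSING = frozenset("?-")


@dataclass
class MorphMatrix:
    """Taxa x characters matrix of single-digit states with '?'/'-' missing."""

    taxa: list[str]
    matrix: np.ndarray  # (n_taxa, n_chars) of single characters

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype="<U1")
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.taxa):
            raise ValueError("matrix shape does not match taxon list")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        valid = set("0123456789") | _MISSING
        bad = set(np.unique(self.matrix)) - valid
        if bad:
            raise ValueError(f"invalid morphological symbols: {sorted(bad)}")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_chars(self) -> int:
        return self.matrix.shape[1]

    def state_masks(self) -> np.ndarray:
        """(n_taxa, n_chars) uint16 bitmasks; missing = all states."""
        masks = np.full(self.matrix.shape, _FULL_MASK, dtype=np.uint16)
        for s in range(MAX_STATES):
            masks[self.matrix == str(s)] = np.uint16(1 << s)
        return masks

    @classmethod
    def from_rows(cls, pairs: Sequence[tuple[str, str]]) -> "MorphMatrix":
        taxa = [p[0] for p in pairs]
        rows = [list(p[1]) for p in pairs]
        return cls(taxa, np.array(rows, dtype="<U1"))


# -- I/O --------------------------------------------------------------------

def read_morph_nexus(path) -> MorphMatrix:
    """Read a NEXUS DATA/CHARACTERS block (symbols 0-9, '?' missing)."""
    cm = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
    pairs = []
    for taxon in cm.taxon_namespace:
        seq = cm[taxon]
        pairs.append((taxon.label, "".join(str(c) for c in seq.symbols_as_list())))
    return MorphMatrix.from_rows(pairs)


def read_morph_tsv(path) -> MorphMatrix:
    pairs = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        taxon, states = line.split("\t")
        pairs.append((taxon, states))
    return MorphMatrix.from_rows(pairs)


def write_morph_tsv(morph: MorphMatrix, path) -> None:
    lines = [f"{t}\t{''.join(row)}" for t, row in zip(morph.taxa, morph.matrix)]
    Path(path).write_text("\n".join(lines) + "\n")


# -- Fitch length -----------------------------------------------------------

def fitch_length(tree: dendropy.Tree, morph: MorphMatrix) -> int:
    """Minimum number of unordered state changes over all characters.

    Requires a binary tree (every internal node with exactly two children);
    multifurcations are rejected rather than silently resolved.
    """
    labels = leaf_labels(tree)
    missing = labels - set(morph.taxa)
    if missing:
        raise ValueError(f"tree leaves without data rows: {sorted(missing)}")
    masks = morph.state_masks()
    row_of = {t: i for i, t in enumerate(morph.taxa)}
    length = np.zeros(morph.n_chars, dtype=np.int64)
    sets: dict[int, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        children = node.child_nodes()
        if not children:
            sets[id(node)] = masks[row_of[node.taxon.label]]
            continue
        if len(children) != 2:
            raise ValueError("fitch_length requires a strictly binary tree")
        s1 = sets.pop(id(children[0]))
        s2 = sets.pop(id(children[1]))
        inter = s1 & s2
        empty = inter == 0
        length += empty
        sets[id(node)] = np.where(empty, s1 | s2, inter)
    return int(length.sum())


# -- constrained NNI refinement ---------------------------------------------

def _induced_backbone_canonical(tree: dendropy.Tree,
                                constraints: CladeConstraintSet) -> str:
    """Canonical form of the backbone induced on one representative per clade."""
    reps = {min(taxa): label for label, taxa in constraints.clades.items()}
    sub = tree.extract_tree_with_taxa_labels(list(reps))

    def canon(node):  # extracted tree shares taxa; map labels, never mutate
        if node.is_leaf():
            return reps[node.taxon.label]
        return "(" + ",".join(sorted(canon(c) for c in node.child_nodes())) + ")"

    return canon(sub.seed_node) + ";"


def _constraints_satisfied(tree: dendropy.Tree,
                           constraints: CladeConstraintSet,
                           backbone_canonical: str) -> bool:
    for taxa in constraints.clades.values():
        if not is_monophyletic(tree, taxa):
            return False
    if constraints.outgroup and len(constraints.outgroup) > 1:
        if not is_monophyletic(tree, constraints.outgroup):
            return False
    return _induced_backbone_canonical(tree, constraints) == backbone_canonical


def _nni_moves(tree: dendropy.Tree):
    """(u, v, child, sibling) tuples for every rooted NNI on internal edges."""
    moves = []
    for v in tree.preorder_internal_node_iter():
        u = v.parent_node
        if u is None:
            continue
        siblings = [c for c in u.child_nodes() if c is not v]
        if len(siblings) != 1:
            continue
        s = siblings[0]
        for child in v.child_nodes():
            moves.append((u, v, child, s))
    return moves


def _apply_swap(u, v, child, s):
    v.remove_child(child)
    u.remove_child(s)
    v.add_child(s)
    u.add_child(child)


def constrained_best_length(
    morph: MorphMatrix,
    constraints: CladeConstraintSet,
    backbone: dendropy.Tree,
    within_clade_subtrees: Mapping[str, dendropy.Tree],
    outgroup_subtree: dendropy.Tree | None = None,
    seed: int = 0,
) -> tuple[int, dendropy.Tree]:
    """Shortest tree found by constraint-preserving NNI from the grafted start.

    Returns (length, tree) at the local optimum; the length never exceeds
    that of the initial backbone-constrained tree. Move order is shuffled by
    ``seed``, making the refinement deterministic for a given seed.
    """
    tree = build_constrained_tree(backbone, within_clade_subtrees,
                                  outgroup_subtree)
    tree = parse_newick(canonical_newick(tree))  # drop lengths; stable order
    backbone_canon = canonical_newick(backbone)
    rng = np.random.default_rng(seed)
    best = fitch_length(tree, morph)
    improved = True
    while improved:
        improved = False
        moves = _nni_moves(tree)
        for m in rng.permutation(len(moves)):
            u, v, child, s = moves[m]
            _apply_swap(u, v, child, s)
            ok = _constraints_satisfied(tree, constraints, backbone_canon)
            new_len = fitch_length(tree, morph) if ok else None
            if ok and new_len < best:
                best = new_len
                improved = True
                break
            _apply_swap(u, v, s, child)  # undo
    return best, tree


def write_length_table(rows: Sequence[tuple[str, int]], path) -> None:
    lines = ["topology\tparsimony_length"]
    lines += [f"{name}\t{length}" for name, length in rows]
    Path(path).write_text("\n".join(lines) + "\n")
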