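"""Synthetic data: trees, nucleotide gene sets with controlled conflicting
signal, occupancy-degraded supermatrices, and Mk-model morphological
matrices.

The generator mirrors the structure of small multi-locus datasets: a pool of
loci simulated on one of two competing topologies (mixing proportion
``prop_tree1``), with per-locus occupancy imposed by masking whole taxa —
the way GenBank loci are typically missing for entire taxa — until each
locus's realized occupancy falls inside a configured range. Masked taxa are
emitted as runs of ``?`` so every locus shares one taxon namespace. All
outputs are byte-reproducible from the configuration seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
from dendropy.model import birthdeath

from .alignment import Alignment, PartitionEntry, PartitionScheme, write_fasta
from .substmodel import STATES, SubstitutionModel
from .likelihood import TreeIndex
from .trees import (
    CladeConstraintSet,
    build_constrained_tree,
    enumerate_backbones,
    leaf_labels,
    parse_newick,
    write_newick,
)

__all__ = [
    "SimConfig",
    "GeneTruth",
    "simulate_yule_tree",
    "simulate_alignment",
    "simulate_gene_set",
    "simulate_morph_matrix",
    "simulate_clade_tree_pair",
    "export_gene_set",
]


@dataclass(frozen=True)
class GeneTruth:
    """Ground truth for one simulated locus."""

    gene_id: str
    source_topology: str  # "T1" or "T2"
    realized_occupancy: float


@dataclass
class SimConfig:
    """Study conditions for the synthetic gene-set generator.

    Defaults emulate a small multi-locus dataset of the kind assembled from
    GenBank: ~28 taxa in four clades plus outgroup, four loci, occupancy
    spanning 0.25-0.96, and weak deep signal (short backbone branches).
    """

    n_taxa: int = 28
    clade_assignment: dict[str, str] | None = None
    n_genes: int = 4
    sites_per_gene: int | tuple[int, int] = (400, 900)
    prop_tree1: float = 0.5
    branch_scale: float = 1.0
    occupancy_range: tuple[float, float] = (0.25, 0.96)
    model: SubstitutionModel = field(default_factory=SubstitutionModel.jc)
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 1 or self.n_genes < 1:
            raise ValueError("counts must be at least 1")
        if not 0.0 <= self.prop_tree1 <= 1.0:
            raise ValueError("prop_tree1 must lie in [0, 1]")
        lo, hi = self.occupancy_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("occupancy_range must satisfy 0 < low <= high <= 1")
        if isinstance(self.sites_per_gene, int):
            if self.sites_per_gene < 1:
                raise ValueError("sites_per_gene must be positive")
        else:
            a, b = self.sites_per_gene
            if not (1 <= a <= b):
                raise ValueError("sites_per_gene range must satisfy 1 <= low <= high")


# -- trees ------------------------------------------------------------------

def simulate_yule_tree(
    n_taxa: int,
    seed: int,
    branch_scale: float = 1.0,
    labels: list[str] | None = None,
) -> dendropy.Tree:
    """Pure-birth (Yule) tree with unit speciation rate, rescaled.

    Branch lengths are multiplied by ``branch_scale`` so they read as
    expected substitutions per site. Leaves are labeled ``t1..tn`` unless
    explicit labels are given.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if labels is not None and len(labels) != n_taxa:
        raise ValueError("label count must equal n_taxa")
    rng = random.Random(int(seed))
    tree = birthdeath.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_taxa,
        rng=rng,
    )
    # the process stops exactly at the n-th split, leaving zero-length tips;
    # run it on for the Exp(n) waiting time to the next (uncounted) split
    extra = rng.expovariate(n_taxa)
    for lf in tree.leaf_node_iter():
        lf.edge.length = (lf.edge.length or 0.0) + extra
    if labels is None:
        labels = [f"t{i + 1}" for i in range(n_taxa)]
    # assign labels in random order so labeled shapes are exchangeable
    shuffled = list(labels)
    rng.shuffle(shuffled)
    for lf, lab in zip(tree.leaf_node_iter(), shuffled):
        lf.taxon.label = lab
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = max(edge.length * branch_scale, 0.0)
    tree.seed_node.edge.length = None
    return parse_newick(write_newick(tree))


# -- sequence simulation ----------------------------------------------------

def simulate_alignment(
    tree: dendropy.Tree,
    model: SubstitutionModel,
    n_sites: int,
    seed,
) -> Alignment:
    """Evolve ``n_sites`` i.i.d. nucleotide sites along the tree.

    Gamma rate heterogeneity (when configured on the model) assigns each
    site one of the discrete category rates with equal probability.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be positive")
    rng = np.random.default_rng(seed)
    ti = TreeIndex(tree)
    bl = ti.extract_branch_lengths()
    rates = model.category_rates
    site_rate_idx = (
        rng.integers(0, rates.size, n_sites) if rates.size > 1
        else np.zeros(n_sites, dtype=int)
    )
    states = np.empty((ti.n_nodes, n_sites), dtype=np.int8)
    root = ti.root_index
    states[root] = rng.choice(4, size=n_sites, p=model.base_frequencies)
    preorder = list(reversed(range(ti.n_nodes)))
    parent = np.full(ti.n_nodes, -1)
    for i, kids in enumerate(ti.children):
        for c in kids:
            parent[c] = i
    for i in preorder:
        if i == root:
            continue
        p_states = states[parent[i]]
        for k, rate in enumerate(rates):
            mask = site_rate_idx == k
            if not mask.any():
                continue
            P = model.transition_probs(bl[i], rate)
            cum = P.cumsum(axis=1)
            u = rng.random(int(mask.sum()))
            states[i, mask] = (u[:, None] > cum[p_states[mask]]).sum(axis=1)
    leaf_rows = states[ti.leaf_indices]
    chars = np.array(list(STATES))[leaf_rows]
    order = np.argsort(ti.leaf_labels)
    return Alignment(
        [ti.leaf_labels[i] for i in order], chars[order]
    )


# -- gene sets with conflicting signal --------------------------------------

def _feasible_mask_counts(n_taxa: int, lo: float, hi: float) -> np.ndarray:
    """Numbers of maskable taxa giving occupancy inside [lo, hi]."""
    m = np.arange(0, n_taxa)  # keep at least one taxon
    occ = (n_taxa - m) / n_taxa
    return m[(occ >= lo) & (occ <= hi)]


def simulate_gene_set(
    t1: dendropy.Tree,
    t2: dendropy.Tree,
    config: SimConfig,
) -> tuple[list[tuple[str, Alignment]], PartitionScheme, list[GeneTruth]]:
    """Simulate loci on a two-topology mixture with occupancy degradation.

    Returns ``(loci, scheme, truths)`` where ``loci`` is a list of
    ``(gene_id, Alignment)`` over the shared taxon set (masked taxa all-'?'),
    ``scheme`` the partition ranges of the corresponding supermatrix, and
    ``truths`` the per-gene generating topology and realized occupancy.
    """
    if leaf_labels(t1) != leaf_labels(t2):
        raise ValueError("T1 and T2 must share an identical leaf set")
    taxa = sorted(leaf_labels(t1))
    n_taxa = len(taxa)
    lo, hi = config.occupancy_range
    feasible = _feasible_mask_counts(n_taxa, lo, hi)
    if feasible.size == 0:
        raise ValueError(
            f"occupancy_range {config.occupancy_range} is infeasible for "
            f"{n_taxa} taxa"
        )
    rng = np.random.default_rng(config.seed)
    on_t1 = rng.random(config.n_genes) < config.prop_tree1
    if isinstance(config.sites_per_gene, int):
        lengths = np.full(config.n_genes, config.sites_per_gene)
    else:
        a, b = config.sites_per_gene
        lengths = rng.integers(a, b + 1, config.n_genes)
    gene_seeds = rng.integers(0, 2**31 - 1, config.n_genes)

    loci: list[tuple[str, Alignment]] = []
    truths: list[GeneTruth] = []
    entries: list[PartitionEntry] = []
    pos = 1
    for g in range(config.n_genes):
        gene_id = f"gene{g + 1}"
        source = t1 if on_t1[g] else t2
        aln = simulate_alignment(
            source, config.model, int(lengths[g]), int(gene_seeds[g])
        )
        aln = aln.subset_taxa(taxa)  # shared sorted namespace
        target = rng.uniform(lo, hi)
        want_m = n_taxa - int(round(target * n_taxa))
        n_mask = int(feasible[np.argmin(np.abs(feasible - want_m))])
        matrix = aln.matrix.copy()
        if n_mask > 0:
            masked = rng.choice(n_taxa, size=n_mask, replace=False)
            matrix[masked] = "?"
        realized = (n_taxa - n_mask) / n_taxa
        assert lo <= realized <= hi
        loci.append((gene_id, Alignment(taxa, matrix)))
        truths.append(GeneTruth(gene_id, "T1" if on_t1[g] else "T2", realized))
        entries.append(PartitionEntry(gene_id, pos, pos + int(lengths[g]) - 1))
        pos += int(lengths[g])
    return loci, PartitionScheme(tuple(entries)), truths


# -- morphological matrices (Mk) --------------------------------------------

def simulate_morph_matrix(
    tree: dendropy.Tree,
    n_chars: int,
    n_states: int,
    seed,
) -> "MorphMatrix":
    """Discrete characters evolved under the Mk model on a tree.

    Branch lengths are expected changes per character; under Mk the chance
    of remaining in the current state over a branch of length ``t`` is
    ``exp(-kt/(k-1)) + (1 - exp(-kt/(k-1)))/k``.
    """
    from .parsimony import MorphMatrix

    if n_states < 2 or n_states > 10:
        raise ValueError("n_states must be between 2 and 10")
    if n_chars < 1:
        raise ValueError("n_chars must be positive")
    rng = np.random.default_rng(seed)
    ti = TreeIndex(tree)
    bl = ti.extract_branch_lengths(default=0.0)
    k = n_states
    states = np.empty((ti.n_nodes, n_chars), dtype=np.int8)
    root = ti.root_index
    states[root] = rng.integers(0, k, n_chars)
    parent = np.full(ti.n_nodes, -1)
    for i, kids in enumerate(ti.children):
        for c in kids:
            parent[c] = i
    for i in reversed(range(ti.n_nodes)):
        if i == root:
            continue
        stay = np.exp(-k * bl[i] / (k - 1))
        redraw = rng.random(n_chars) >= stay
        states[i] = states[parent[i]]
        if redraw.any():
            states[i, redraw] = rng.integers(0, k, int(redraw.sum()))
    leaf_rows = states[ti.leaf_indices]
    chars = leaf_rows.astype("<U1")
    order = np.argsort(ti.leaf_labels)
    return MorphMatrix([ti.leaf_labels[i] for i in order], chars[order])


# -- four-clade scenario helpers --------------------------------------------

def simulate_clade_tree_pair(
    constraints: CladeConstraintSet,
    seed: int,
    backbone_indices: tuple[int, int] = (0, 1),
    within_scale: float = 0.2,
    backbone_branch: float = 0.05,
) -> tuple[dendropy.Tree, dendropy.Tree]:
    """Two full competing topologies sharing within-clade structure.

    Within-clade subtrees are Yule simulations (scaled by ``within_scale``),
    frozen and grafted onto two distinct enumerated backbones; branches
    without simulated lengths (the backbone edges) receive
    ``backbone_branch`` substitutions/site — the knob controlling how much
    deep signal the data carry.
    """
    backbones = enumerate_backbones(constraints.clade_labels)
    i1, i2 = backbone_indices
    if i1 == i2 or max(i1, i2) >= len(backbones):
        raise ValueError("backbone_indices must be two distinct valid indices")
    rng = np.random.default_rng(seed)
    subtrees: dict[str, dendropy.Tree] = {}
    for label in sorted(constraints.clades):
        taxa = sorted(constraints.clades[label])
        if len(taxa) == 1:
            subtrees[label] = parse_newick(f"{taxa[0]};")
        else:
            subtrees[label] = simulate_yule_tree(
                len(taxa), int(rng.integers(0, 2**31 - 1)),
                branch_scale=within_scale, labels=taxa,
            )
    og = sorted(constraints.outgroup)
    og_tree = None
    if og:
        if len(og) == 1:
            og_tree = parse_newick(f"{og[0]};")
        else:
            og_tree = simulate_yule_tree(
                len(og), int(rng.integers(0, 2**31 - 1)),
                branch_scale=within_scale, labels=og,
            )
    trees = []
    for idx in (i1, i2):
        full = build_constrained_tree(backbones[idx], subtrees, og_tree)
        for edge in full.preorder_edge_iter():
            if edge.head_node is full.seed_node:
                continue
            if edge.length is None:
                edge.length = backbone_branch
        trees.append(full)
    return trees[0], trees[1]


# -- export -----------------------------------------------------------------

def export_gene_set(
    outdir,
    loci,
    scheme: PartitionScheme,
    truths: list[GeneTruth],
    t1: dendropy.Tree,
    t2: dendropy.Tree,
    config: SimConfig,
) -> None:
    """Write per-gene FASTAs, supermatrix, partition file, trees, and truth TSV."""
    from .alignment import concatenate, write_partition_file

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for gene_id, aln in loci:
        write_fasta(aln, outdir / f"{gene_id}.fasta")
    supermatrix, _ = concatenate(loci)
    write_fasta(supermatrix, outdir / "supermatrix.fasta")
    write_partition_file(scheme, outdir / "partitions.txt")
    (outdir / "T1.nwk").write_text(write_newick(t1) + "\n")
    (outdir / "T2.nwk").write_text(write_newick(t2) + "\n")
    lines = ["gene_id\tsource_topology\trealized_occupancy"]
    lines += [
        f"{t.gene_id}\t{t.source_topology}\t{t.realized_occupancy:.6g}"
        for t in truths
    ]
    (outdir / "gene_truth.tsv").write_text("\n".join(lines) + "\n")
    (outdir / "sim_seed.txt").write_text(f"seed: {config.seed}\n")
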