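"""Partitioned phylogenetic likelihood: Felsenstein pruning with site patterns,
branch-length optimization on fixed topologies, and candidate-tree fitting.

Per-site log-likelihoods are computed by the pruning algorithm over unique
site patterns, with per-node rescaling and log accumulators so small trees
and deep divergences alike stay in range; ambiguity codes and missing cells
enter as partial likelihood 1 over their compatible states. Branch lengths
are optimized coordinate-wise (bounded scalar search per branch, round-robin
until the total log-likelihood gain drops below tolerance). Partitioned fits
use one proportional branch-length set per candidate tree with per-partition
rate multipliers; substitution-model parameters are estimated once per
partition on a reference topology and then held fixed across candidates, so
site-likelihood differences between candidates reflect topology alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .alignment import Alignment, PartitionScheme
from .substmodel import IUPAC_PARTIALS, SubstitutionModel

logger = logging.getLogger(__name__)

MAX_BRANCH_LENGTH = 10.0
_DEFAULT_INIT_BL = 0.1


# -- tree flattening --------------------------------------------------------

class TreeIndex:
    """Postorder array view of a dendropy tree for fast likelihood passes."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self.postorder: list[dendropy.Node] = list(tree.postorder_node_iter())
        self.index = {id(n): i for i, n in enumerate(self.postorder)}
        self.children: list[list[int]] = [
            [self.index[id(c)] for c in n.child_nodes()] for n in self.postorder
        ]
        self.root_index = self.index[id(tree.seed_node)]
        self.leaf_indices: list[int] = []
        self.leaf_labels: list[str] = []
        for i, n in enumerate(self.postorder):
            if n.is_leaf():
                self.leaf_indices.append(i)
                self.leaf_labels.append(n.taxon.label)
        self.n_nodes = len(self.postorder)
        # branch i = edge above postorder node i; the root's entry is unused
        self.branch_nodes = [i for i in range(self.n_nodes) if i != self.root_index]

    def extract_branch_lengths(self, default: float | None = None) -> np.ndarray:
        bl = np.zeros(self.n_nodes)
        for i in self.branch_nodes:
            length = self.postorder[i].edge.length
            if length is None:
                if default is None:
                    raise ValueError("tree has branches without lengths")
                length = default
            if length < 0:
                raise ValueError("negative branch length")
            bl[i] = length
        return bl

    def inject_branch_lengths(self, bl: np.ndarray) -> dendropy.Tree:
        for i in self.branch_nodes:
            self.postorder[i].edge.length = float(bl[i])
        return self.tree


# -- pruning engine ---------------------------------------------------------

def _leaf_partial_rows(matrix_rows: np.ndarray) -> np.ndarray:
    """(n_leaves, n_patterns) char array -> (n_leaves, n_patterns, 4) indicators."""
    out = np.empty(matrix_rows.shape + (4,))
    for sym, vec in IUPAC_PARTIALS.items():
        mask = matrix_rows == sym
        if mask.any():
            out[mask] = vec
    return out


class PruningEngine:
    """Evaluates site log-likelihoods for one alignment block on one topology.

    Site patterns are compressed once at construction; repeated calls with
    different branch lengths (as during optimization) reuse the compressed
    representation.
    """

    def __init__(self, tree_index: TreeIndex, alignment: Alignment,
                 model: SubstitutionModel):
        self.ti = tree_index
        self.model = model
        missing = set(tree_index.leaf_labels) - set(alignment.taxa)
        if missing:
            raise ValueError(f"tree taxa absent from alignment: {sorted(missing)}")
        rows = np.array([alignment.taxa.index(t) for t in tree_index.leaf_labels])
        sub = alignment.matrix[rows]  # (n_leaves, n_sites)
        patterns, inverse, counts = np.unique(
            sub.T, axis=0, return_inverse=True, return_counts=True
        )
        self.pattern_index = inverse
        self.pattern_weights = counts.astype(float)
        self.n_sites = sub.shape[1]
        self.n_patterns = patterns.shape[0]
        self._leaf_partials = _leaf_partial_rows(patterns.T)  # (leaves, pat, 4)
        self._leaf_slot = {
            node_idx: k for k, node_idx in enumerate(tree_index.leaf_indices)
        }

    def pattern_lnl(self, branch_lengths: np.ndarray,
                    rate_scale: float = 1.0) -> np.ndarray:
        """Per-pattern natural-log likelihoods."""
        ti = self.ti
        model = self.model
        rates = model.category_rates * rate_scale
        ncat = rates.size
        npat = self.n_patterns
        partials: list[np.ndarray | None] = [None] * ti.n_nodes
        log_scale = np.zeros(npat)
        for i, children in enumerate(ti.children):
            if not children:
                L = np.broadcast_to(
                    self._leaf_partials[self._leaf_slot[i]], (ncat, npat, 4)
                ).copy()
            else:
                L = np.ones((ncat, npat, 4))
                for c in children:
                    P = model.transition_probs_stack(branch_lengths[c], rates)
                    L *= partials[c] @ P.transpose(0, 2, 1)
                    partials[c] = None  # free
                smax = L.max(axis=(0, 2))
                if (smax <= 0).any():
                    raise ValueError("zero partial likelihood (numeric error)")
                L /= smax[None, :, None]
                log_scale += np.log(smax)
            partials[i] = L
        root = partials[ti.root_index]
        site_like = (root @ model.base_frequencies).mean(axis=0)  # (npat,)
        if (site_like <= 0).any() or not np.isfinite(site_like).all():
            raise ValueError("non-finite site likelihood")
        return np.log(site_like) + log_scale

    def site_lnl(self, branch_lengths: np.ndarray,
                 rate_scale: float = 1.0) -> np.ndarray:
        """Per-site log-likelihoods in original column order."""
        return self.pattern_lnl(branch_lengths, rate_scale)[self.pattern_index]

    def total_lnl(self, branch_lengths: np.ndarray,
                  rate_scale: float = 1.0) -> float:
        return float(
            self.pattern_lnl(branch_lengths, rate_scale) @ self.pattern_weights
        )

    # -- cached upper/lower partials for fast per-branch optimization ------
    def edge_pass(self, branch_lengths: np.ndarray,
                  rate_scale: float = 1.0) -> dict:
        """Lower (D) and upper (E) partials for every branch.

        For node ``v`` with parent ``u``, ``D[v][c,p,j]`` is the likelihood
        of data below ``v`` given state ``j`` at ``v``; ``E[v][c,p,i]`` the
        likelihood of all remaining data given state ``i`` at ``u``
        (stationary frequencies folded in at the root). The site likelihood
        as a function of the branch length ``t`` above ``v`` is then
        ``sum_ij E[v][i] P(t)[i,j] D[v][j]``, averaged over categories, times
        ``exp(S[v])`` per pattern — so a scalar search over ``t`` touches
        only one 4x4 transition matrix.
        """
        ti = self.ti
        model = self.model
        rates = model.category_rates * rate_scale
        ncat = rates.size
        npat = self.n_patterns
        D: list[np.ndarray | None] = [None] * ti.n_nodes
        SD = [None] * ti.n_nodes  # per-pattern log scale below node
        M: list[np.ndarray | None] = [None] * ti.n_nodes  # P(t_v) @ D_v
        for i, children in enumerate(ti.children):
            if not children:
                D[i] = np.broadcast_to(
                    self._leaf_partials[self._leaf_slot[i]], (ncat, npat, 4)
                )
                SD[i] = np.zeros(npat)
            else:
                L = np.ones((ncat, npat, 4))
                S = np.zeros(npat)
                for c in children:
                    P = model.transition_probs_stack(branch_lengths[c], rates)
                    M[c] = D[c] @ P.transpose(0, 2, 1)
                    L = L * M[c]
                    S += SD[c]
                smax = L.max(axis=(0, 2))
                if (smax <= 0).any():
                    raise ValueError("zero partial likelihood (numeric error)")
                L /= smax[None, :, None]
                S += np.log(smax)
                D[i], SD[i] = L, S
        E: list[np.ndarray | None] = [None] * ti.n_nodes
        SE = [None] * ti.n_nodes
        H: list[np.ndarray | None] = [None] * ti.n_nodes
        SH = [None] * ti.n_nodes
        root = ti.root_index
        H[root] = np.broadcast_to(model.base_frequencies,
                                  (ncat, npat, 4))
        SH[root] = np.zeros(npat)
        for u in reversed(range(ti.n_nodes)):  # preorder (parents first)
            kids = ti.children[u]
            if not kids or H[u] is None:
                continue
            for v in kids:
                Ev = H[u].copy()
                Sv = SH[u].copy()
                for s in kids:
                    if s is v:
                        continue
                    Ev = Ev * M[s]
                    Sv = Sv + SD[s]
                emax = Ev.max(axis=(0, 2))
                emax[emax <= 0] = 1.0
                Ev /= emax[None, :, None]
                Sv = Sv + np.log(emax)
                E[v], SE[v] = Ev, Sv
                if ti.children[v]:
                    P = model.transition_probs_stack(branch_lengths[v], rates)
                    H[v] = Ev @ P
                    SH[v] = Sv
        scale = {
            v: SD[v] + SE[v] for v in ti.branch_nodes
        }
        return {"D": D, "E": E, "S": scale, "rates": rates}

    def edge_total_lnl(self, ctx: dict, v: int, t: float) -> float:
        """Total lnL as a function of one branch length, from cached partials."""
        P = self.model.transition_probs_stack(t, ctx["rates"])
        like = ((ctx["E"][v] @ P) * ctx["D"][v]).sum(axis=(0, 2)) / ctx["rates"].size
        if (like <= 0).any():
            return -np.inf
        return float((np.log(like) + ctx["S"][v]) @ self.pattern_weights)


# -- public single-block operations ----------------------------------------

def site_log_likelihoods(tree: dendropy.Tree, alignment: Alignment,
                         model: SubstitutionModel) -> np.ndarray:
    """Per-site ln-likelihood of the alignment on a tree with branch lengths."""
    ti = TreeIndex(tree)
    engine = PruningEngine(ti, alignment, model)
    return engine.site_lnl(ti.extract_branch_lengths())


def total_log_likelihood(tree: dendropy.Tree, alignment: Alignment,
                         model: SubstitutionModel) -> float:
    return float(site_log_likelihoods(tree, alignment, model).sum())


def _optimize_branches_engine(
    engines: Sequence[PruningEngine],
    rate_scales: Sequence[float],
    bl: np.ndarray,
    branch_nodes: Sequence[int],
    tol: float,
    max_rounds: int,
) -> tuple[np.ndarray, float]:
    """Coordinate-wise branch optimization over summed engine likelihoods.

    Each branch is optimized by bounded scalar search against cached
    upper/lower partials (one fresh tree pass per branch), so a single
    likelihood evaluation inside the search touches only one transition
    matrix per engine.
    """

    def total(vec: np.ndarray) -> float:
        return sum(
            e.total_lnl(vec, s) for e, s in zip(engines, rate_scales)
        )

    current = total(bl)
    for _ in range(max_rounds):
        start = current
        for b in branch_nodes:
            ctxs = [e.edge_pass(bl, s) for e, s in zip(engines, rate_scales)]

            def neg(x: float) -> float:
                return -sum(
                    e.edge_total_lnl(ctx, b, x)
                    for e, ctx in zip(engines, ctxs)
                )

            res = minimize_scalar(
                neg, bounds=(0.0, MAX_BRANCH_LENGTH), method="bounded",
                options={"xatol": 1e-6},
            )
            if -res.fun > current:
                bl[b] = res.x
                current = -res.fun
        if current - start < tol:
            return bl, current
    logger.warning("branch-length optimization hit max rounds without converging")
    return bl, current


def optimize_branch_lengths(
    tree: dendropy.Tree,
    alignment: Alignment,
    model: SubstitutionModel,
    tol: float = 1e-6,
    max_rounds: int = 20,
) -> tuple[dendropy.Tree, float]:
    """ML branch lengths on a fixed topology; returns (tree, total lnL).

    The input tree is modified in place (lengths only) and returned. Missing
    input lengths start at 0.1 substitutions/site. The returned lnL never
    falls below the starting lnL.
    """
    ti = TreeIndex(tree)
    engine = PruningEngine(ti, alignment, model)
    bl = ti.extract_branch_lengths(default=_DEFAULT_INIT_BL)
    bl, lnl = _optimize_branches_engine(
        [engine], [1.0], bl, ti.branch_nodes, tol, max_rounds
    )
    ti.inject_branch_lengths(bl)
    return tree, lnl


# -- model parameter estimation ---------------------------------------------

def empirical_base_frequencies(alignment: Alignment) -> np.ndarray:
    counts = np.array([
        (alignment.matrix == s).sum() for s in "ACGT"
    ], dtype=float)
    counts += (alignment.matrix == "U").sum() * np.array([0, 0, 0, 1.0])
    if counts.sum() == 0:
        return np.full(4, 0.25)
    # pseudo-count keeps frequencies strictly positive
    counts += 0.5
    return counts / counts.sum()


def _pack_model(family: str, gamma: bool):
    """Number of free parameters and (vector -> model kwargs) decoder."""
    n_ex = {"JC": 0, "HKY": 1, "GTR": 5}[family]

    def decode(theta: np.ndarray, freqs: np.ndarray,
               n_categories: int) -> SubstitutionModel:
        ex = np.ones(6)
        if family == "HKY":
            kappa = np.exp(theta[0])
            ex = np.array([1.0, kappa, 1.0, 1.0, kappa, 1.0])
        elif family == "GTR":
            ex[:5] = np.exp(theta[:5])  # GT exchangeability fixed at 1
        shape = np.exp(theta[n_ex]) if gamma else None
        fr = np.full(4, 0.25) if family == "JC" else freqs
        return SubstitutionModel(ex, fr, shape, n_categories)

    return n_ex + (1 if gamma else 0), decode


def estimate_model(
    alignment: Alignment,
    tree: dendropy.Tree,
    family: str = "GTR",
    gamma: bool = True,
    n_categories: int = 4,
    tol: float = 1e-4,
    n_outer: int = 2,
) -> tuple[SubstitutionModel, float]:
    """Estimate substitution parameters on a fixed reference topology.

    Frequencies are empirical; exchangeabilities (family-dependent) and the
    gamma shape are optimized by Nelder-Mead on log scale, alternating with
    branch-length rounds. Returns the fitted model and the final lnL.
    """
    family = family.upper()
    if family not in {"JC", "HKY", "GTR"}:
        raise ValueError(f"unknown model family: {family}")
    freqs = empirical_base_frequencies(alignment)
    n_free, decode = _pack_model(family, gamma)
    theta = np.zeros(n_free)
    ti = TreeIndex(tree)
    bl = ti.extract_branch_lengths(default=_DEFAULT_INIT_BL)
    model = decode(theta, freqs, n_categories)
    lnl = -np.inf
    for _ in range(n_outer):
        engine = PruningEngine(ti, alignment, model)
        bl, lnl = _optimize_branches_engine(
            [engine], [1.0], bl, ti.branch_nodes, tol, max_rounds=10
        )
        if n_free == 0:
            break

        def neg(th: np.ndarray) -> float:
            try:
                m = decode(th, freqs, n_categories)
            except ValueError:
                return np.inf
            return -PruningEngine(ti, alignment, m).total_lnl(bl)

        res = minimize(neg, theta, method="Nelder-Mead",
                       options={"xatol": 1e-3, "fatol": tol, "maxiter": 200})
        theta = res.x
        model = decode(theta, freqs, n_categories)
        lnl = -res.fun
    ti.inject_branch_lengths(bl)
    return model, float(lnl)


# -- site-lnL matrix --------------------------------------------------------

@dataclass
class SiteLnLMatrix:
    """Candidate-trees x sites matrix of per-site log-likelihoods."""

    tree_ids: list[str]
    site_lnl: np.ndarray  # (n_trees, n_sites)
    partition_scheme: PartitionScheme | None = None
    models: dict = field(default_factory=dict)
    fitted_trees: dict = field(default_factory=dict)

    def __post_init__(self):
        self.site_lnl = np.asarray(self.site_lnl, dtype=float)
        if self.site_lnl.ndim != 2 or self.site_lnl.shape[0] != len(self.tree_ids):
            raise ValueError("site_lnl must be (n_trees, n_sites)")
        if not np.isfinite(self.site_lnl).all():
            raise ValueError("non-finite site log-likelihoods")

    @property
    def n_trees(self) -> int:
        return len(self.tree_ids)

    @property
    def n_sites(self) -> int:
        return self.site_lnl.shape[1]

    def total_lnl(self) -> np.ndarray:
        return self.site_lnl.sum(axis=1)

    def row(self, tree_id: str) -> np.ndarray:
        return self.site_lnl[self.tree_ids.index(tree_id)]

    def ml_tree_id(self) -> str:
        return self.tree_ids[int(np.argmax(self.total_lnl()))]

    # -- ".sitelh"-style I/O ------------------------------------------------
    def write_sitelh(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.n_trees} {self.n_sites}\n")
            for tid, row in zip(self.tree_ids, self.site_lnl):
                fh.write(tid + " " + " ".join(f"{v:.10g}" for v in row) + "\n")

    @classmethod
    def read_sitelh(cls, path,
                    partition_scheme: PartitionScheme | None = None) -> "SiteLnLMatrix":
        lines = Path(path).read_text().splitlines()
        n_trees, n_sites = map(int, lines[0].split())
        ids, rows = [], []
        for line in lines[1:1 + n_trees]:
            parts = line.split()
            ids.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
        mat = np.array(rows)
        if mat.shape != (n_trees, n_sites):
            raise ValueError("sitelh file dimensions do not match header")
        return cls(ids, mat, partition_scheme)


# -- partitioned candidate fitting ------------------------------------------

def _partition_alignments(alignment: Alignment,
                          scheme: PartitionScheme) -> dict[str, Alignment]:
    return {
        e.locus_id: alignment.subset_columns(e.column_indices()) for e in scheme
    }


def fit_candidates(
    alignment: Alignment,
    scheme: PartitionScheme | None,
    candidates: Mapping[str, dendropy.Tree],
    model_family: str = "GTR",
    gamma: bool = True,
    n_categories: int = 4,
    tol: float = 1e-4,
    max_rounds: int = 10,
) -> SiteLnLMatrix:
    """Fit every candidate topology and collect site-wise log-likelihoods.

    Model parameters (and per-partition rate multipliers) are estimated once
    on the first candidate and held fixed; each candidate then receives its
    own proportional branch-length optimization. Rows of the result are the
    concatenated per-partition site-lnL vectors in supermatrix column order.
    """
    if not candidates:
        raise ValueError("no candidate trees supplied")
    if scheme is None:
        from .alignment import PartitionEntry
        scheme = PartitionScheme(
            (PartitionEntry("all", 1, alignment.n_columns),)
        )
    blocks = _partition_alignments(alignment, scheme)
    ids = list(candidates)
    ref_id = ids[0]

    # 1. per-partition model estimation on the reference topology
    models: dict[str, SubstitutionModel] = {}
    if model_family.upper() == "JC" and not gamma:
        models = {locus: SubstitutionModel.jc() for locus in blocks}
    else:
        for locus, block in blocks.items():
            ref_tree = dendropy.Tree(candidates[ref_id])  # working copy
            models[locus], _ = estimate_model(
                block, ref_tree, model_family, gamma, n_categories, tol
            )

    # 2. reference fit: shared branch lengths + per-partition rate multipliers
    ref_tree = dendropy.Tree(candidates[ref_id])
    ti = TreeIndex(ref_tree)
    engines = [PruningEngine(ti, blocks[e.locus_id], models[e.locus_id])
               for e in scheme]
    multipliers = np.ones(len(scheme))
    bl = ti.extract_branch_lengths(default=_DEFAULT_INIT_BL)
    for _ in range(2):
        bl, _ = _optimize_branches_engine(
            engines, multipliers, bl, ti.branch_nodes, tol, max_rounds
        )
        if len(scheme) == 1:
            break
        for k, engine in enumerate(engines):
            res = minimize_scalar(
                lambda m, _e=engine: -_e.total_lnl(bl, m),
                bounds=(1e-3, 100.0), method="bounded",
                options={"xatol": 1e-6},
            )
            multipliers[k] = res.x
        # identifiability: site-weighted mean multiplier folded into lengths
        weights = np.array([e.n_sites for e in scheme], dtype=float)
        mean_m = float((multipliers * weights).sum() / weights.sum())
        multipliers /= mean_m
        bl *= mean_m

    # 3. per-candidate branch lengths at fixed models and multipliers
    rows = np.empty((len(ids), scheme.n_columns))
    fitted: dict[str, dendropy.Tree] = {}
    for r, tid in enumerate(ids):
        tree = dendropy.Tree(candidates[tid])
        cti = TreeIndex(tree)
        cengines = [PruningEngine(cti, blocks[e.locus_id], models[e.locus_id])
                    for e in scheme]
        cbl = bl.copy() if tid == ref_id else cti.extract_branch_lengths(
            default=_DEFAULT_INIT_BL
        )
        cbl, _ = _optimize_branches_engine(
            cengines, multipliers, cbl, cti.branch_nodes, tol, max_rounds
        )
        for e, engine, m in zip(scheme, cengines, multipliers):
            rows[r, e.start - 1:e.end] = engine.site_lnl(cbl, m)
        cti.inject_branch_lengths(cbl)
        fitted[tid] = tree
    model_meta = {locus: m.to_dict() for locus, m in models.items()}
    model_meta["_rate_multipliers"] = dict(zip(scheme.locus_ids, multipliers.tolist()))
    return SiteLnLMatrix(ids, rows, scheme, models=model_meta, fitted_trees=fitted)
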