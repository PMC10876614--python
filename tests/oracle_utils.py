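"""Independent oracles used by the test suite.

These deliberately avoid the package's pruning/Fitch code paths: transition
matrices come from scipy's matrix exponential, likelihoods from exhaustive
summation over internal-state assignments, and parsimony scores from a
Sankoff dynamic program and from brute-force minimization over internal
states.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.linalg import expm

_STATE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _allowed_states(symbol: str) -> list[int]:
    if symbol in _STATE_INDEX:
        return [_STATE_INDEX[symbol]]
    return [0, 1, 2, 3]  # '?', '-', N treated as fully ambiguous


def brute_force_site_lnl(tree, alignment, model) -> np.ndarray:
    """Per-site lnL by summing over all internal-state assignments.

    Transition matrices are computed with scipy.linalg.expm from the
    normalized generator, independently of the package's eigendecomposition.
    """
    nodes = list(tree.postorder_node_iter())
    idx = {id(n): i for i, n in enumerate(nodes)}
    root = idx[id(tree.seed_node)]
    internal = [i for i, n in enumerate(nodes) if not n.is_leaf()]
    leaves = [i for i, n in enumerate(nodes) if n.is_leaf()]
    parent = {}
    blen = {}
    for n in nodes:
        for c in n.child_nodes():
            parent[idx[id(c)]] = idx[id(n)]
            blen[idx[id(c)]] = c.edge.length
    taxon_row = {t: r for r, t in enumerate(alignment.taxa)}
    rates = model.category_rates
    Q = model.rate_matrix
    pi = model.base_frequencies
    n_sites = alignment.n_columns
    out = np.zeros(n_sites)
    for site in range(n_sites):
        site_like = 0.0
        for rate in rates:
            P = {
                i: expm(Q * blen[i] * rate) for i in parent
            }
            cat_like = 0.0
            for assign in itertools.product(range(4), repeat=len(internal)):
                states = dict(zip(internal, assign))
                term = pi[states[root]]
                for i in internal:
                    if i != root:
                        term *= P[i][states[parent[i]], states[i]]
                for i in leaves:
                    lbl = nodes[i].taxon.label
                    sym = alignment.matrix[taxon_row[lbl], site]
                    term *= sum(
                        P[i][states[parent[i]], s] for s in _allowed_states(sym)
                    )
                cat_like += term
            site_like += cat_like / len(rates)
        out[site] = np.log(site_like)
    return out


def sankoff_length(tree, morph) -> int:
    """Parsimony length by the Sankoff DP with unit costs."""
    k = 10
    big = 10**6
    taxon_row = {t: r for r, t in enumerate(morph.taxa)}
    total = 0
    for char in range(morph.n_chars):
        costs = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                sym = morph.matrix[taxon_row[node.taxon.label], char]
                c = np.full(k, big)
                if sym in "?-":
                    c[:] = 0
                else:
                    c[int(sym)] = 0
            else:
                c = np.zeros(k)
                for child in node.child_nodes():
                    cc = costs[id(child)]
                    # staying costs cc[s]; changing costs min(cc) + 1
                    c = c + np.minimum(cc, cc.min() + 1)
            costs[id(node)] = c
        total += int(costs[id(tree.seed_node)].min())
    return total


def brute_force_parsimony(tree, morph) -> int:
    """Minimum changes over all internal-state assignments, per character."""
    nodes = list(tree.postorder_node_iter())
    idx = {id(n): i for i, n in enumerate(nodes)}
    internal = [i for i, n in enumerate(nodes) if not n.is_leaf()]
    taxon_row = {t: r for r, t in enumerate(morph.taxa)}
    edges = []
    for n in nodes:
        for c in n.child_nodes():
            edges.append((idx[id(n)], idx[id(c)]))
    total = 0
    for char in range(morph.n_chars):
        observed = {
            int(s)
            for s in morph.matrix[:, char]
            if s not in "?-"
        } or {0}
        states_pool = sorted(observed)
        leaf_states = {}
        for i, n in enumerate(nodes):
            if n.is_leaf():
                sym = morph.matrix[taxon_row[n.taxon.label], char]
                leaf_states[i] = states_pool if sym in "?-" else [int(sym)]
        best = 10**9
        for assign in itertools.product(states_pool, repeat=len(internal)):
            st = dict(zip(internal, assign))
            cost = 0
            ok = True
            for u, v in edges:
                if v in leaf_states:
                    cost += min(0 if s == st[u] else 1 for s in leaf_states[v])
                else:
                    cost += 0 if st[u] == st[v] else 1
                if cost >= best:
                    ok = False
                    break
            if ok:
                best = cost
        total += best
    return total
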