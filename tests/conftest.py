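"""Shared fixtures: small trees, models, and a four-clade synthetic scenario."""

from __future__ import annotations

import numpy as np
import pytest

import phylosignal as ps
from phylosignal.trees import CladeConstraintSet


@pytest.fixture(scope="session")
def jc():
    return ps.SubstitutionModel.jc()


@pytest.fixture()
def toy_alignment():
    return ps.Alignment.from_sequences([
        ("A", "ACGTACGT"),
        ("B", "ACGTACGA"),
        ("C", "ACGAACGT"),
        ("D", "TCGAACGT"),
    ])


@pytest.fixture(scope="session")
def four_clade_constraints() -> CladeConstraintSet:
    clades = {
        f"C{i}": frozenset(f"C{i}_{j}" for j in range(1, 4)) for i in range(1, 5)
    }
    return CladeConstraintSet(clades, frozenset(["OUT_1", "OUT_2"]))


@pytest.fixture(scope="session")
def clade_tree_pair(four_clade_constraints):
    return ps.simulate_clade_tree_pair(
        four_clade_constraints, seed=11, backbone_branch=0.08
    )


@pytest.fixture(scope="session")
def gene_set(clade_tree_pair):
    """Six-locus mixture with occupancy degradation (shared across tests)."""
    t1, t2 = clade_tree_pair
    config = ps.SimConfig(
        n_taxa=14,
        n_genes=6,
        sites_per_gene=(200, 400),
        prop_tree1=0.7,
        occupancy_range=(0.5, 1.0),
        seed=5,
    )
    loci, scheme, truths = ps.simulate_gene_set(t1, t2, config)
    return loci, scheme, truths, config


@pytest.fixture(scope="session")
def six_taxon_pair():
    """Two NNI-related 6-taxon topologies with moderate divergence."""
    t1 = ps.parse_newick(
        "(((a:0.2,b:0.2):0.15,(c:0.2,d:0.2):0.15):0.1,(e:0.2,f:0.2):0.1);"
    )
    t2 = ps.parse_newick(
        "(((a:0.2,c:0.2):0.15,(b:0.2,d:0.2):0.15):0.1,(e:0.2,f:0.2):0.1);"
    )
    return t1, t2


@pytest.fixture(scope="session")
def dgls_recovery_run():
    """200 loci at 70/30 mixture on strong signal, fitted once for dGLS tests.

    Session-scoped because the partitioned fit over 200 loci is the
    expensive step shared by the signal-recovery checks.
    """
    from phylosignal.experiments import dgls_recovery

    return dgls_recovery(n_genes=200, sites_per_gene=500,
                         prop_tree1=0.7, seed=20)
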