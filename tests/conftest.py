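"""Shared fixtures: small seeded simulations reused across test modules."""

import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", message=".*Bio.codonalign.*")

from wgdscan import simulate


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20150361)


@pytest.fixture(scope="session")
def small_history():
    """Two sister species from a planted WGD (Ks 1.0) with moderate
    fractionation; big enough for block detection, small enough to be fast."""
    cfg = simulate.SimulationConfig(
        seed=11,
        n_scaffolds=3,
        genes_per_scaffold=20,
        gene_length_codons=200,
        retention_prob=0.7,
        read_depth=0.0001,  # reads unused here
    )
    return simulate.run_simulation(cfg)


@pytest.fixture(scope="session")
def loss_history():
    """One species with a deleted receptor and one unannotated receptor,
    with 20x reads; its sister keeps every gene intact."""
    cfg = simulate.SimulationConfig(
        seed=7,
        n_scaffolds=2,
        genes_per_scaffold=10,
        gene_length_codons=200,
        species_tree="(spA,spB);",
        branch_ks={"spA": 0.02, "spB": 0.02},
        read_depth=20.0,
        loss_events=[
            simulate.LossEvent(frozenset({"spA"}), "DRD1E", "delete_sequence"),
            simulate.LossEvent(frozenset({"spA"}), "DRD4", "drop_annotation"),
        ],
    )
    return simulate.run_simulation(cfg)


def ortholog_pairs(result, sp1, sp2):
    """Gene-id pairs for orthologs shared by two leaf species."""
    ids2 = {g.gene_id for g in result.species_genomes[sp2].genes()}
    out = []
    for g in result.species_genomes[sp1].genes():
        partner = f"{sp2}|{g.gene_id.split('|', 1)[1]}"
        if partner in ids2:
            out.append((g.gene_id, partner))
    return out
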