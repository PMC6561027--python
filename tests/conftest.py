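"""Shared fixtures: small ground-truthed synthetic worlds.

Everything is generated at test time from fixed seeds; the expensive
desk-scale recovery world is session-scoped so the unit and acceptance
suites share one simulation.
"""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from predfit import ExpansionFitnessModel
from predfit import simulate as sim


@pytest.fixture(scope="session")
def small_genome():
    """10 kb genome with 10 genes, fixed seed."""
    cfg = sim.SimConfig(
        genome_length=10_000, n_genes=10, gene_length_range=(300, 600), seed=7,
        n_insertions=100,
    )
    genome, genes = sim.gen_genome(cfg)
    return cfg, genome, genes


@pytest.fixture(scope="session")
def recovery_world():
    """Desk-scale parameter-recovery world: 2,000 insertions over 200 genes
    (10 essential), d=100, depth 2e6, 3 replicates, seed 1."""
    cfg = sim.SimConfig(
        genome_length=300_000,
        n_genes=200,
        n_insertions=2000,
        read_depth=2_000_000,
        n_replicates=3,
        seed=1,
    )
    genome, genes = sim.gen_genome(cfg)
    fitness_map, essential = sim.fitness_landscape(genes["gene_id"], seed=1)
    cfg = dataclasses.replace(cfg, true_fitness=fitness_map, essential_genes=essential)
    sites, truth = sim.gen_library(genome, genes, cfg)
    table = sim.simulate_expansion(
        truth, d=100.0, depth=cfg.read_depth, n_replicates=3, seed=1
    )
    results = ExpansionFitnessModel(table, d=100.0, genes=genes["gene_id"]).fit()
    true_w = pd.Series(fitness_map, name="true_W").reindex(genes["gene_id"]).fillna(1.0)
    return {
        "config": cfg,
        "genome": genome,
        "genes": genes,
        "truth": truth,
        "table": table,
        "results": results,
        "true_w": true_w,
        "essential": essential,
    }


@pytest.fixture(scope="session")
def readback_world():
    """Small world for exact read round-trips: 300 sites, 20 kb, depth 2e4."""
    cfg = sim.SimConfig(
        genome_length=40_000,
        n_genes=20,
        n_insertions=300,
        read_depth=20_000,
        n_replicates=1,
        seed=3,
    )
    genome, genes = sim.gen_genome(cfg)
    sites, truth = sim.gen_library(genome, genes, cfg)
    table = sim.simulate_expansion(truth, d=100.0, depth=20_000, n_replicates=1, seed=3)
    return {"genome": genome, "genes": genes, "truth": truth, "table": table}


@pytest.fixture(scope="session")
def pool_worlds():
    """Attachment and rounding sorting simulations with known probabilities:
    100 mutants spanning [0, 0.5] plus 10 bulk-like controls, depth 1e6,
    six replicates."""
    out = {}
    for which, score_type in (("attach", "attachment"), ("round", "rounding")):
        truth = sim.make_pool_truth(100, 10, which=which, seed=1)
        if which == "attach":
            table = sim.simulate_sorting(truth, depth=1_000_000, seed=1, n_replicates=6)
        else:
            table = sim.simulate_bdelloplast(
                truth, contamination=0.02, depth=1_000_000, seed=1, n_replicates=6
            )
        out[score_type] = (truth, table)
    return out
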