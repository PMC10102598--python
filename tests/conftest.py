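"""Shared fixtures: hand-built toy data plus simulated datasets at three scales.

The large fixtures are session-scoped so the acceptance-style recovery
tests share one simulation each:

* ``sim_small``  — 200 genes / 5,000 strains; fast unit-level checks.
* ``null_sim``   — 3,400 genes / 80,000 strains, 21 Time0 samples in three
  groups plus one condition with planted effects spanning [-3, 1]; used for
  null calibration, essentiality recovery and fitness parameter recovery.
* ``module_sim`` — 1,200 genes / 30,000 strains, 32 conditions with planted
  co-regulated modules and condition-specific effects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import barseqfit as bf
from barseqfit.genome import GENE_COLUMNS


def make_genome(n_genes=5, length=1000, gap=100, gc=0.6, nonrep=None, replicon="chromosome"):
    """Equal-length, equal-GC toy genome on a single main chromosome."""
    rows = []
    pos = 0
    for i in range(n_genes):
        begin = pos + gap + 1
        end = begin + length - 1
        pos = end
        rows.append(
            (f"t{i:03d}", replicon, begin, end, "+", gc,
             length if nonrep is None else nonrep[i], "toy gene")
        )
    genes = pd.DataFrame(rows, columns=GENE_COLUMNS)
    return bf.GenomeModel([bf.Replicon(replicon, pos + gap, True)], genes)


def make_pool(genome, inserts):
    """Pool from explicit (replicon, pos, n_reads) insertion records."""
    rows = [
        (f"BC{i:05d}" + "A" * 13, rep, "+", pos, reads)
        for i, (rep, pos, reads) in enumerate(inserts)
    ]
    strains = pd.DataFrame(rows, columns=["barcode", "replicon", "strand", "pos", "n_reads"])
    return bf.InsertionPool(strains).annotate(genome)


@pytest.fixture(scope="session")
def toy5():
    """Five equal genes with 2, 4, 6, 8, 10 central insertion positions."""
    genome = make_genome(5)
    inserts = []
    for i, n_central in enumerate([2, 4, 6, 8, 10]):
        begin = genome.genes.loc[i, "begin"]
        for k in range(n_central):
            # positions spread inside the central 10-90% window
            inserts.append(("chromosome", begin + 150 + 60 * k, 1))
    return genome, make_pool(genome, inserts)


@pytest.fixture(scope="session")
def sim_small():
    genome, truth = bf.simulate_genome(200, essential_fraction=0.12,
                                       plasmid_gene_fraction=0.05, seed=11)
    pool = bf.simulate_pool(genome, truth, 5000, seed=12)
    design = bf.ExperimentDesign.build(["condA"], n_time0=3, replicates=2)
    bf.plant_random_effects(truth, ["condA"], fraction=0.2, seed=13)
    counts = bf.simulate_counts(pool, truth, design, depth=200_000, seed=14)
    return {"genome": genome, "truth": truth, "pool": pool,
            "design": design, "counts": counts}


@pytest.fixture(scope="session")
def sim_small_results(sim_small):
    model = bf.FitnessModel(sim_small["counts"], sim_small["design"],
                            sim_small["pool"], sim_small["genome"])
    return model.fit()


@pytest.fixture(scope="session")
def null_sim():
    genome, truth = bf.simulate_genome(3400, essential_fraction=0.12,
                                       plasmid_gene_fraction=0.06, seed=101)
    pool = bf.simulate_pool(genome, truth, 80_000, seed=102)
    rows = []
    for gi in range(3):
        for i in range(7):
            rows.append((f"G{gi}.T0r{i + 1}", "Time0", f"G{gi}", "Time0", i + 1))
    rows.append(("recov.r1", "condition", "G0", "recov", 1))
    design = bf.ExperimentDesign(
        pd.DataFrame(rows, columns=["sample", "role", "time0_group", "condition", "replicate"])
    )
    bf.plant_random_effects(truth, ["recov"], fraction=0.2, low=-3.0, high=1.0, seed=103)
    counts = bf.simulate_counts(pool, truth, design, depth=1_000_000, seed=104)
    return {"genome": genome, "truth": truth, "pool": pool,
            "design": design, "counts": counts}


@pytest.fixture(scope="session")
def null_sim_results(null_sim):
    model = bf.FitnessModel(null_sim["counts"], null_sim["design"],
                            null_sim["pool"], null_sim["genome"])
    return model.fit()


@pytest.fixture(scope="session")
def module_sim():
    genome, truth = bf.simulate_genome(1200, essential_fraction=0.12,
                                       plasmid_gene_fraction=0.06, seed=201)
    pool = bf.simulate_pool(genome, truth, 30_000, seed=202)
    conditions = [f"c{i:02d}" for i in range(32)]
    bf.plant_modules(truth, conditions, n_modules=6, genes_per_module=8,
                     signal_sd=1.5, noise_sd=0.3, seed=203)
    bf.plant_specific_effects(truth, conditions, n_genes=25, magnitude=-2.0, seed=204)
    design = bf.ExperimentDesign.build(conditions, n_time0=3, replicates=1)
    counts = bf.simulate_counts(pool, truth, design, depth=1_000_000, seed=205)
    results = bf.FitnessModel(counts, design, pool, genome).fit()
    return {"genome": genome, "truth": truth, "pool": pool, "design": design,
            "counts": counts, "results": results}
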