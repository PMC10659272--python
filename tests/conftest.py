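"""Shared fixtures: one default synthetic corpus reused across the suite.

Everything is generated programmatically with fixed seeds; the heavier
corpus-level fixtures are session-scoped so each is built once.
"""

from __future__ import annotations

import numpy as np
import pytest

from brainaging.mutation_spectra import build_spectrum
from brainaging.signature_inference import spectra_matrix
from brainaging.synthetic_data import (
    GeneratorConfig,
    make_toy_genome,
    simulate_expression,
    simulate_mutation_catalog,
)

CORPUS_SEED = 1


@pytest.fixture(scope="session")
def gen_config() -> GeneratorConfig:
    return GeneratorConfig(seed=CORPUS_SEED)


@pytest.fixture(scope="session")
def toy_genome(gen_config):
    return make_toy_genome(gen_config)


@pytest.fixture(scope="session")
def catalog(gen_config, toy_genome):
    genome, genes, mask = toy_genome
    return simulate_mutation_catalog(gen_config, genome, genes, mask)


@pytest.fixture(scope="session")
def per_cell_spectra(catalog, toy_genome):
    genome, _, _ = toy_genome
    records, _ = catalog
    by_cell: dict[str, list] = {}
    for m in records:
        by_cell.setdefault(m.cell_id, []).append(m)
    return {cell: build_spectrum(muts, genome)[0] for cell, muts in sorted(by_cell.items())}


@pytest.fixture(scope="session")
def spectra_and_ages(per_cell_spectra, gen_config):
    V, cells = spectra_matrix(per_cell_spectra)
    ages = np.array([gen_config.donor_ages[int(c[1:3]) - 1] for c in cells])
    return V, cells, ages


@pytest.fixture(scope="session")
def expression(gen_config, toy_genome):
    _, genes, _ = toy_genome
    return simulate_expression(gen_config, genes)


@pytest.fixture(scope="session")
def de_results(expression):
    from brainaging.transcriptome_aging import de_by_cell_type

    cm, _ = expression
    return de_by_cell_type(cm)


@pytest.fixture(scope="session")
def annotated_catalog(catalog, toy_genome):
    from brainaging.genomic_enrichment import annotate_mutations

    genome, genes, _ = toy_genome
    records, _ = catalog
    return annotate_mutations(records, genes, genome)


@pytest.fixture(scope="session")
def tiny_reference():
    # 61 bp toy chromosome with all-ACGT content for context unit tests
    seq = "ATCGTACCGTTAGCATCCGATCGATTACGCGTAACGTAGCTAGCTTACGATCGTACGGTAC"
    return {"chr1": seq}
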