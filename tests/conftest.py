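"""Shared fixtures: small synthetic datasets and hand-built matrices."""

from __future__ import annotations

import numpy as np
import pytest

from popdiff.data_model import GenotypeMatrix, PopulationPanel, Variant
from popdiff.synthetic_data import GeneratorConfig, generate


def make_matrix(rows, sample_pops, chrom="chr1", start_pos=100, ancestral=None):
    """Build a GenotypeMatrix from a list of haplotype rows.

    sample_pops: list of population labels, one per sample (two haplotype
    entries per sample in each row).
    """
    rows = np.asarray(rows, dtype=np.int8)
    n_samples = rows.shape[1] // 2
    sample_ids = [f"{p}{i}" for i, p in enumerate(sample_pops)]
    variants = [
        Variant(
            chrom=chrom,
            pos=start_pos + 10 * i,
            ref="A",
            alt="G",
            ancestral=(ancestral[i] if ancestral else "A"),
        )
        for i in range(rows.shape[0])
    ]
    matrix = GenotypeMatrix(variants=variants, haplotypes=rows, sample_ids=sample_ids)
    panel = PopulationPanel(assignment=dict(zip(sample_ids, sample_pops)))
    return matrix, panel


@pytest.fixture(scope="session")
def small_dataset():
    """A modest synthetic dataset sized for eQTL power in recovery tests."""
    cfg = GeneratorConfig(
        seed=2024,
        n_variants=1500,
        samples_per_pop=(150, 150, 150),
        expression_samples=(("EUR", 100), ("AFR", 45)),
        n_genes=40,
        chrom_lengths=(("chr1", 2_000_000), ("chr2", 2_000_000)),
        hub_n_targets=15,
    )
    return generate(cfg)


@pytest.fixture(scope="session")
def tiny_dataset():
    """A very small dataset for structural/IO checks."""
    cfg = GeneratorConfig(
        seed=5,
        n_variants=300,
        samples_per_pop=(30, 30, 30),
        expression_samples=(("EUR", 20), ("AFR", 10)),
        n_genes=12,
        chrom_lengths=(("chr1", 600_000), ("chr2", 600_000)),
        hub_n_targets=5,
    )
    return generate(cfg)
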