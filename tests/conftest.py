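"""Shared fixtures: small simulated datasets and random-object factories."""

from __future__ import annotations

import numpy as np
import pytest

from halopop import simpop
from halopop.variants import GenotypeMatrix, Locus


@pytest.fixture(scope="session")
def small_dataset() -> simpop.SimulatedDataset:
    """A small recombining population with planted clones and a
    two-orientation mating locus, reused across test modules."""
    cfg = simpop.SimConfig(
        population_size=80,
        genome=[400_000, 400_000],
        mu=3e-6,
        rho=5e-6,
        generations=300,
        sample_size=15,
        clone_spec=[(0, 2, 10.0), (1, 1, 10.0)],
        gene_windows=[(0, 20_001 + i * 90_000, 100_000 + i * 90_000) for i in range(4)],
        mat_locus=(1, 150_001, 180_000, 0.27),
        lineage_divergence=1500.0,
        seed=11,
    )
    return simpop.simulate_population(cfg)


def random_genotype_matrix(
    rng: np.random.Generator,
    n_samples: int,
    n_loci: int,
    missing_rate: float = 0.0,
    contig: str = "c1",
) -> GenotypeMatrix:
    """Random biallelic-coded matrix with strictly increasing positions."""
    positions = np.sort(
        rng.choice(np.arange(1, max(n_loci * 50, n_loci + 1)), n_loci, replace=False)
    )
    calls = rng.integers(0, 2, size=(n_samples, n_loci)).astype(np.int16)
    if missing_rate > 0:
        calls[rng.random(calls.shape) < missing_rate] = -1
    loci = [Locus(contig, int(p), "A", ("G",)) for p in positions]
    return GenotypeMatrix(
        sample_ids=[f"S{i}" for i in range(n_samples)],
        loci=loci,
        calls=calls,
        contigs=[(contig, int(positions[-1]) + 10)],
    )


def random_binary_tree_newick(rng: np.random.Generator, labels: list[str]) -> str:
    """Random unrooted binary topology via random sequential joining."""
    nodes = [f"{lab}" for lab in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        merged = f"({nodes[i]},{nodes[j]})"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return f"({nodes[0]},{nodes[1]},{nodes[2]});"
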