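"""Shared fixtures: published worked-example cell tables and random datasets.

The two cell tables below are the 2-locus genotype cells of the chronic-
dialysis study's reported best models (cases:controls per cell); rebuilt as
executable datasets they reproduce every published statistic exactly.
"""

import numpy as np
import pytest

from mdrer import GenotypeDataset, synthetic

# SNPs(40,56): four observed cells, 193 cases / 704 controls in total.
CELLS_40_56 = {
    (0, 0): (114, 342),
    (0, 1): (57, 280),
    (1, 0): (5, 27),
    (1, 1): (17, 55),
}

# SNPs(55,64): three observed cells, same totals.
CELLS_55_64 = {
    (0, 0): (174, 689),
    (0, 1): (5, 4),
    (1, 0): (14, 11),
}

N_CASES = 193
N_CONTROLS = 704


@pytest.fixture(scope="session")
def study_fixture_40_56() -> GenotypeDataset:
    return synthetic.fixture_from_cells(CELLS_40_56, n_pad_snps=2, seed=0)


@pytest.fixture(scope="session")
def study_fixture_55_64() -> GenotypeDataset:
    return synthetic.fixture_from_cells(CELLS_55_64, n_pad_snps=2, seed=1)


def random_dataset(
    seed: int,
    n_rows: int = 60,
    n_snps: int = 6,
    case_fraction: float = 0.4,
) -> GenotypeDataset:
    """Unstructured random dataset (no planted effect) for oracle checks."""
    rng = np.random.default_rng(seed)
    genotypes = rng.integers(0, 3, size=(n_rows, n_snps))
    labels = (rng.random(n_rows) < case_fraction).astype(int)
    # guarantee both classes are present
    labels[0], labels[1] = 1, 0
    names = tuple(f"S{i}" for i in range(n_snps))
    return GenotypeDataset(names, genotypes, labels)
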