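import numpy as np
import pytest

from simpa.genome_bins import BinSet
from simpa.reference import ReferenceExperiment, ReferenceMatrix
from simpa.synthetic import SyntheticSpec, default_benchmark


@pytest.fixture(scope="session")
def benchmark():
    """The standard synthetic benchmark (3 types x 10 experiments, seed 1)."""
    return default_benchmark()


@pytest.fixture(scope="session")
def small_benchmark():
    """A fast 2-type reference for end-to-end tests."""
    from simpa.synthetic import generate_reference

    spec = SyntheticSpec(
        n_cell_types=2,
        experiments_per_type=6,
        signature_bins=60,
        shared_bins=40,
        background_bins=80,
        modules_per_type=3,
        modules_per_experiment=1,
        seed=7,
    )
    return generate_reference(spec)


def make_reference(rows, biosamples=None, target="MARK", bin_size=5000):
    """Hand-build a ReferenceMatrix from a dict accession -> bin-index list."""
    keys = sorted({("chrT", i) for bins in rows.values() for i in bins})
    col = {k: j for j, k in enumerate(keys)}
    values = np.zeros((len(rows), len(keys)), dtype=np.uint8)
    experiments = []
    for r, (acc, bins) in enumerate(sorted(rows.items())):
        for i in bins:
            values[r, col[("chrT", i)]] = 1
        biosample = (biosamples or {}).get(acc, "tissueA")
        experiments.append(ReferenceExperiment(acc, target, biosample, "testasm"))
    return ReferenceMatrix(target, experiments, keys, values, bin_size, "testasm")


@pytest.fixture
def tiny_reference():
    """4 experiments x 5 bins with mixed column frequencies."""
    return make_reference(
        {
            "E1": [0, 1, 2],
            "E2": [1, 2, 3],
            "E3": [1, 3, 4],
            "E4": [0, 1, 4],
        },
        biosamples={"E1": "liver", "E2": "liver", "E3": "brain", "E4": "brain"},
    )


def binset(indices, bin_size=5000, chrom="chrT", assembly="testasm"):
    return BinSet([(chrom, i) for i in indices], bin_size, assembly)
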