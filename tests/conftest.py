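import numpy as np
import pytest

from posdist.io_formats import MotifModel
from posdist.pipeline import PipelineConfig, run_full
from posdist.synthetic_data import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A 30-gene, 4-motif synthetic dataset shared across module tests."""
    return generate_dataset(SyntheticSpec(seed=7, n_genes=30, n_motifs=4))


@pytest.fixture(scope="session")
def small_report(small_dataset):
    ds = small_dataset
    return run_full(
        PipelineConfig(seed=7),
        ds.genomes,
        ds.genes,
        ds.motifs,
        ds.ortholog_table,
        expression=ds.expression,
        dhs_peaks=ds.dhs_peaks,
        chip_peaks=ds.chip_peaks,
    )


@pytest.fixture
def sharp_motif():
    """Width-8 motif with one strongly preferred base per position."""
    rows = []
    for dom in (0, 1, 2, 3, 0, 2, 1, 3):
        row = [0.04, 0.04, 0.04, 0.04]
        row[dom] = 0.88
        rows.append(row)
    return MotifModel("sharp", "TFX", "bZIP", np.array(rows))


@pytest.fixture
def uniform_motif():
    return MotifModel("flat", "TFU", "MYB", np.full((4, 4), 0.25))
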