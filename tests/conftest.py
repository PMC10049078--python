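import numpy as np
import pytest

from peplib import (
    DefectRates,
    SyntheticLibraryConfig,
    sample_true_library,
    simulate_reads,
    write_fastq,
)

NO_DEFECTS = DefectRates(0.0, 0.0, 0.0, 0.0, 0.0)


@pytest.fixture
def clean_config():
    """Small error-free library: every simulated read must survive cleaning."""
    return SyntheticLibraryConfig(
        true_diversity=50, seed=11, defect_rates=NO_DEFECTS
    )


@pytest.fixture
def defect_config():
    """Small library with the default mixture of defect classes."""
    return SyntheticLibraryConfig(true_diversity=50, seed=11)


@pytest.fixture
def simulated_fastq(tmp_path, defect_config):
    """A simulated dataset on disk plus its ground truth."""
    pool = sample_true_library(defect_config)
    records, log = simulate_reads(pool, 2000)
    path = tmp_path / "reads.fastq"
    write_fastq(records, path)
    return path, pool, log
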