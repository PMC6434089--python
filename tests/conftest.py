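import pytest

from sccnv import (CbsConfig, CallingConfig, PipelineConfig, synthetic_grid,
                   synthetic_band_table)
from sccnv.genomes import simulation_chrom_lengths
from sccnv.grid import make_window_grid

#: genome scale used throughout the suite (10% hg19, 20-kb windows)
SCALE = 0.1
#: the 4-Mbp event-size filter co-scaled with the genome
MIN_SIZE_SCALED = int(4_000_000 * SCALE)


@pytest.fixture(scope="session")
def scaled_grid():
    return synthetic_grid(scale=SCALE)


@pytest.fixture(scope="session")
def band_table():
    return synthetic_band_table(SCALE)


@pytest.fixture(scope="session")
def chrom_lengths():
    return simulation_chrom_lengths(SCALE)


@pytest.fixture
def small_grid():
    return make_window_grid({"chr1": 100_000, "chr2": 50_000}, 20_000)


def fast_cbs(seed=0, **kw):
    kw.setdefault("n_permutations", 2000)
    return CbsConfig(seed=seed, **kw)


def scaled_calling(**kw):
    kw.setdefault("min_size_bp", MIN_SIZE_SCALED)
    return CallingConfig(**kw)


def scaled_pipeline_config(seed=0, sample_sex=None):
    return PipelineConfig(seed=seed, sample_sex=sample_sex,
                          cbs=fast_cbs(seed=seed),
                          calling=scaled_calling())
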