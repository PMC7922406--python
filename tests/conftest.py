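import numpy as np
import pytest

from dkaryo.genome_bins import build_bins
from dkaryo.pipeline import PanelBundle
from dkaryo.simulate import SimConfig, simulate_panel, synthetic_gc

# A reduced genome keeps panel/pipeline tests fast while preserving the
# autosome + X + Y structure the sex-aware normalization needs.
SMALL_SIZES = {"1": 12_000_000, "2": 8_000_000, "X": 6_000_000, "Y": 3_000_000}
SMALL_TARGET = 100_000


@pytest.fixture(scope="session")
def small_binset():
    bs = build_bins(SMALL_SIZES, None, SMALL_TARGET)
    return bs.with_gc(list(synthetic_gc(bs)))


@pytest.fixture(scope="session")
def small_config(small_binset):
    # ~1500 reads per autosomal bin: strong per-bin Z for constructed events
    return SimConfig(binset=small_binset, mean_filtered_reads=300_000, seed=11,
                     chrom_sizes=dict(SMALL_SIZES))


@pytest.fixture(scope="session")
def small_panel(small_config):
    return simulate_panel(small_config, n=40)


@pytest.fixture(scope="session")
def small_bundle(small_panel, small_binset):
    return PanelBundle.fit(small_panel, small_binset, SMALL_SIZES)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
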