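import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from scarchor.genomic_io import GenomeLayout, make_read_frame
from scarchor.synthetic_data import SimConfig, build_landscape


@pytest.fixture
def layout():
    return GenomeLayout({"chr1": 100_000, "chr2": 50_000}, spike_prefix="dm6_")


@pytest.fixture
def small_cfg():
    """Desk-scale config for fast unit tests (reduced genome and depth)."""
    return SimConfig(
        n_chroms=2,
        chrom_length=4_000_000,
        iz_spacing=4_000_000,
        nascent_span=200_000,
        ip_depth=200_000,
        input_depth=100_000,
        seed=11,
    )


@pytest.fixture
def small_landscape(small_cfg):
    return build_landscape(small_cfg)


def random_reads(layout, n, seed, origin="target"):
    rng = np.random.default_rng(seed)
    names = list(layout.chrom_sizes)
    idx = rng.integers(0, len(names), n)
    lens = np.array([layout.chrom_sizes[c] for c in names])
    start = (rng.random(n) * (lens[idx] - 150)).astype(np.int64)
    strand = np.where(rng.random(n) < 0.5, "+", "-")
    return make_read_frame(
        np.array(names, dtype=object)[idx], start, start + 150, strand, origin
    )


# full-scale studies are expensive; share them across acceptance and
# invariant tests
@pytest.fixture(scope="session")
def wt_study_full():
    from scarchor.pipelines import scar_preset_study

    return scar_preset_study("wt", seed=1)


@pytest.fixture(scope="session")
def treated_study_full():
    from scarchor.pipelines import scar_preset_study

    return scar_preset_study("dpole4-mcm2-2a", seed=1)


@pytest.fixture(scope="session")
def chor_study_full():
    from scarchor.pipelines import chor_preset_study

    return chor_preset_study(seed=1)
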