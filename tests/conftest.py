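"""Shared fixtures: synthetic bundles at the study's default conditions.

The default bundle (3 x 2 Mb genome, 100+100 planted DMRs at fold 4,
2e5 fragments per passage, seed 1) is generated once per session; a reduced
bundle serves the cheaper unit tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from senesceq.dmr_calling import call_dmrs
from senesceq.genome_regions import GenomeSpec
from senesceq.synthetic_data import (
    SyntheticConfig,
    generate_genome_bundle,
    lad_signal_config,
)

SMALL_CONFIG = dict(
    chrom_length=400_000,
    n_lads=8,
    lad_length=(10_000, 40_000),
    n_hyper=20,
    n_hypo=20,
    n_genes=120,
    fragments_per_sample=60_000,
    n_mark_domains=10,
    mark_length=(3_000, 15_000),
    mark_fragments=30_000,
    n_probes=1_200,
)


@pytest.fixture(scope="session")
def default_bundle():
    return generate_genome_bundle(seed=1)


@pytest.fixture(scope="session")
def default_calls(default_bundle):
    hyper = call_dmrs(
        default_bundle.fragments_late, default_bundle.fragments_early, direction="hyper"
    )
    hypo = call_dmrs(
        default_bundle.fragments_early, default_bundle.fragments_late, direction="hypo"
    )
    return {"hyper": hyper, "hypo": hypo}


@pytest.fixture(scope="session")
def lad_bundle():
    """Bundle with methyl-capture signal attenuated inside LADs."""
    return generate_genome_bundle(lad_signal_config(), seed=1)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(**SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_genome_bundle(small_config, seed=11)


@pytest.fixture()
def toy_genome():
    return GenomeSpec(("chr1", "chr2"), (10_000, 5_000))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
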