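"""Shared synthetic fixtures (all generated, seeded, session-scoped)."""

import numpy as np
import pytest

from mutopo.fixtures import (toy_binning, toy_reference_cohort,
                             toy_reference_model)
from mutopo.ingest import SampleMeta, build_count_tensor
from mutopo.inference import FitConfig, fit
from mutopo.simulate import SimulationSpec, simulate_cohort

SMALL_CHROMS = {"chr1": 100_000, "chr2": 80_000, "chr3": 80_000}


@pytest.fixture(scope="session")
def small_world():
    """A small 260-kb genome with tracks, binning and sequences."""
    binning, genome = toy_binning(seed=11, chrom_lengths=SMALL_CHROMS)
    return binning, genome


@pytest.fixture(scope="session")
def small_binning(small_world):
    return small_world[0]


@pytest.fixture(scope="session")
def small_genome(small_world):
    return small_world[1]


@pytest.fixture(scope="session")
def ref_model(small_binning):
    return toy_reference_model(small_binning, K=3, seed=11)


@pytest.fixture(scope="session")
def ref_pool():
    return toy_reference_cohort(3, seed=11)


@pytest.fixture(scope="session")
def small_cohort(ref_model, ref_pool, small_world):
    binning, genome = small_world
    exposures, burdens = ref_pool
    spec = SimulationSpec(ref_model, exposures, burdens, n_samples=20,
                          gamma=1.0, seed=21)
    mutations, truth, meta = simulate_cohort(spec, binning, genome)
    return mutations, truth, meta


@pytest.fixture(scope="session")
def small_tensor(small_cohort, small_world):
    binning, genome = small_world
    mutations, _, meta = small_cohort
    samples = [SampleMeta(r.sample_id, r.purity) for r in meta.itertuples()]
    return build_count_tensor(mutations, binning, genome, samples)


@pytest.fixture(scope="session")
def fitted_small(small_tensor, small_binning):
    cfg = FitConfig(K=3, seed=5, max_epochs=30)
    model, state = fit(small_tensor, small_binning, cfg)
    return model, state, cfg


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
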