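import pytest

from mthet import LocusMap, MaskSet, MtReference, run_sample
from mthet.simulate import SimSampleConfig, simulate_sample


@pytest.fixture(scope="session")
def reference():
    return MtReference.synthetic()


@pytest.fixture(scope="session")
def locus_map():
    return LocusMap.default()


@pytest.fixture(scope="session")
def masks():
    return MaskSet.default()


@pytest.fixture(scope="session")
def sim_small(reference):
    """One simulated sample: 4 cells, modest somatic load, fixed seed."""
    cfg = SimSampleConfig(seed=1234, sample="patient01", n_cells=4, somatic_rate=40.0)
    return simulate_sample(cfg, reference=reference)


@pytest.fixture(scope="session")
def pipeline_small(sim_small, reference, locus_map, masks):
    return run_sample(
        sim_small.cells, sim_small.consensus, reference, locus_map, masks
    )
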