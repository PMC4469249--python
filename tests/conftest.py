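import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from srnakit.io_formats import MatureReference, SmallRNARead
from srnakit.pipeline import process_library
from srnakit.synthetic_data import default_config, simulate_dataset

SEED = 1234


@pytest.fixture(scope="session")
def sim_config():
    # small libraries keep the unit/property suite quick; the acceptance
    # suite re-runs at full size
    return default_config(library_size=4000, seed=SEED)


@pytest.fixture(scope="session")
def dataset(sim_config):
    return simulate_dataset(sim_config)


@pytest.fixture(scope="session")
def processed(dataset, sim_config):
    """Full pipeline output for every simulated tissue."""
    out = {}
    for tissue, (records, _truth) in dataset.libraries.items():
        raw = [
            SmallRNARead(sequence=seq, tissue=tissue, mean_quality=40.0)
            for _rid, seq, _q in records
        ]
        out[tissue] = process_library(raw, tissue, sim_config.adapter, dataset.refs)
    return out


@pytest.fixture(scope="session")
def small_refs():
    """Hand-sized reference set with pairwise-distinct 10-nt prefixes."""
    return [
        MatureReference(id="dre-miR-1-3p", sequence="TGGAATGTAAAGAAGTATGTAT"),
        MatureReference(id="dre-miR-122-5p", sequence="TGGAGTGTGACAATGGTGTTTG"),
        MatureReference(id="fru-miR-462-5p", sequence="GTAACGGAACCCATAATGCAGCT"),
        MatureReference(id="dre-miR-206-3p", sequence="TGGAACGTACGGAATTTCATAA"),
    ]
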