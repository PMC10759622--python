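import logging

import pytest

from cnvpop.genome import build_genome
from cnvpop.pipeline import PipelineConfig, run_pipeline
from cnvpop.simulate import PopulationDesign, PlantedLocus

logging.getLogger("cnvpop").setLevel(logging.WARNING)


@pytest.fixture
def small_genome():
    """One 4 Mb chromosome (10,000 bins of 400 bp)."""
    return build_genome([4_000_000], bin_size=400)


@pytest.fixture
def two_pop_design(small_genome):
    """Two populations of 5, one common DEL and one common DUP locus."""
    loci = (
        PlantedLocus("chr1", 100_001, 104_000, "DEL", {"A": 0.6, "B": 0.6}, "del1"),
        PlantedLocus("chr1", 500_001, 504_000, "DUP", {"A": 0.6, "B": 0.6}, "dup1"),
    )
    return PopulationDesign(populations=(("A", 5), ("B", 5)), loci=loci)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the default study-design scenario.

    Session-scoped: several test modules score different aspects of the
    same run (calls, genotypes, scan tables, outputs on disk).
    """
    outdir = tmp_path_factory.mktemp("default_run")
    config = PipelineConfig(seed=20_240_401)
    results = run_pipeline(config, outdir)
    return {"config": config, "outdir": outdir, **results}
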