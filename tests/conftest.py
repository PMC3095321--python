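import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from h3k4seq.annotations_io import GeneModel, Genome
from h3k4seq.coverage import CoverageTrack

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def toy_genome() -> Genome:
    return Genome({"chr1": 10_000, "chr2": 5_000})


@pytest.fixture
def toy_genes(toy_genome) -> list[GeneModel]:
    return [
        GeneModel("g1", "chr1", 1000, 3000, "+"),
        GeneModel("g2", "chr1", 4000, 5500, "-"),
        GeneModel("g3", "chr2", 500, 2000, "+"),
    ]


def make_track(genome: Genome, fill=0.0, mark="H3K4me3", condition="watered") -> CoverageTrack:
    data = {c: np.full(length, float(fill)) for c, length in genome.items()}
    return CoverageTrack(mark=mark, condition=condition, data=data, total_reads=None)


@pytest.fixture
def flat_track(toy_genome) -> CoverageTrack:
    return make_track(toy_genome, fill=3.0)
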