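import pytest

from dopseqkit import GenomicInterval, ReferenceIndex, SimulationScenario
from dopseqkit.simulate import PlantedRegion


def iv(chrom, start, end):
    return GenomicInterval(chrom, start, end)


@pytest.fixture
def five_region_scenario():
    """20 Mb chromosome with five planted regions of 0.2-2 Mb, extra copies 1-6."""

    def make(seed: int) -> SimulationScenario:
        ref = ReferenceIndex({"chr1": 20_000_000})
        regions = [
            PlantedRegion(iv("chr1", 1_000_000, 3_000_000), 1),
            PlantedRegion(iv("chr1", 5_000_000, 6_000_000), 2),
            PlantedRegion(iv("chr1", 8_000_000, 8_600_000), 3),
            PlantedRegion(iv("chr1", 12_000_000, 12_350_000), 4),
            PlantedRegion(iv("chr1", 16_000_000, 16_200_000), 6),
        ]
        return SimulationScenario(reference=ref, planted_regions=regions, seed=seed)

    return make


@pytest.fixture
def null_scenario():
    """Background-only scenario: no planted regions at all."""

    def make(seed: int) -> SimulationScenario:
        return SimulationScenario(
            reference=ReferenceIndex({"chr1": 20_000_000}),
            planted_regions=[],
            seed=seed,
        )

    return make
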