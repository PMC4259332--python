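import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from oriflex import (  # noqa: E402
    GenomeModel,
    GenomicInterval,
    OriginAnnotation,
    OriginSimParams,
    ProbeTrack,
)


@pytest.fixture(scope="session")
def reference_pair():
    """(wild-type, seven-origin-deleted) genome models for chrVI + chrIII."""
    from oriflex import datasets

    wt = datasets.reference_genome(("chrVI", "chrIII"))
    mutant, _ = datasets.origin_depleted_genome(("chrVI", "chrIII"))
    return wt, mutant


@pytest.fixture()
def toy_genome():
    """Small single-chromosome genome with one efficient origin at 50 kb."""
    return GenomeModel(
        {"toy": 100_000},
        [
            OriginAnnotation(
                "TOY1",
                GenomicInterval("toy", 49_900, 50_100),
                sim=OriginSimParams(50_000.0, 0.8, orc_height=2.5),
            )
        ],
        background_regions=[GenomicInterval("toy", 90_000, 98_000)],
    )


def make_track(values, chrom="toy", start=1, step=8, **metadata):
    values = np.asarray(values, dtype=float)
    positions = start + step * np.arange(len(values))
    return ProbeTrack(chrom, positions, values, dict(metadata))


@pytest.fixture()
def random_track():
    rng = np.random.default_rng(7)
    return make_track(rng.normal(0.3, 0.5, size=400))
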