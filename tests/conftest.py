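import numpy as np
import pytest

import tfrmotifs as tm
from tfrmotifs.synthetic import (
    PlantedMotif,
    SyntheticSpec,
    generate_dataset,
    make_planted_motif,
)


@pytest.fixture(scope="session")
def curated_table():
    return tm.load_curated_motifs()


@pytest.fixture(scope="session")
def curated_matrices():
    return tm.curated_motif_matrices()


@pytest.fixture(scope="session")
def carriers():
    return tm.synthetic_carrier_sequences()


@pytest.fixture(scope="session")
def carrier_hits(carriers, curated_matrices):
    """Curated motifs scanned over their synthetic carrier proteins."""
    return tm.scan(carriers, curated_matrices)


@pytest.fixture(scope="session")
def small_planted():
    """Two subfamilies, one sharp exclusive motif each: known ground truth."""
    rng = np.random.default_rng(7)
    spec = SyntheticSpec(
        subfamily_sizes={"A": 60, "B": 60},
        subfamily_motifs={
            "A": [PlantedMotif(make_planted_motif(10, 0.95, rng=rng, motif_id="A-1"))],
            "B": [PlantedMotif(make_planted_motif(10, 0.95, rng=rng, motif_id="B-1"))],
        },
        length_range=(100, 150),
        seed=11,
    )
    return generate_dataset(spec)
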