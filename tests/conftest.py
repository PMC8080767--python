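import numpy as np
import pandas as pd
import pytest

from methylresponse.simulate import (
    GroundTruth,
    SimulationConfig,
    generate_annotation,
    make_validation_fixture,
    simulate_methylation,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A small but complete world: 3 promoter DMRs planted among 4000 CpGs."""
    return SimulationConfig(
        seed=11,
        n_cpgs=4000,
        n_genes=40,
        n_enhancers=20,
        planted_dmrs=[(20, -0.25, "promoter")] * 3,
        coupling_strength=2.0,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    annotation, positions = generate_annotation(small_config)
    beta, truth = simulate_methylation(small_config, annotation, positions)
    return {
        "config": small_config,
        "annotation": annotation,
        "positions": positions,
        "beta": beta.sort_by_position(),
        "truth": truth,
    }


@pytest.fixture(scope="session")
def validation_table():
    return make_validation_fixture()


@pytest.fixture()
def toy_intervals():
    """Hand-sized interval frames for overlap tests."""
    query = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr2"],
            "start": [150, 200, 10],
            "end": [250, 250, 20],
        }
    )
    subject = pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr2", "chr3"],
            "start": [100, 240, 0, 5],
            "end": [200, 300, 15, 50],
            "name": ["A", "B", "C", "D"],
        }
    )
    return query, subject


def brute_force_overlaps(query, subject):
    """All-pairs interval scan: the oracle for overlap_any."""
    hits = []
    for qi, q in query.iterrows():
        for si, s in subject.iterrows():
            if q["chrom"] == s["chrom"] and q["start"] < s["end"] and s["start"] < q["end"]:
                hits.append((qi, si))
    return sorted(hits)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
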