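import numpy as np
import pandas as pd
import pytest

from rholandscape.synthetic import (
    GrowthParams,
    make_annotation,
    simulate_growth_curves,
    simulate_tiling_array,
)


@pytest.fixture(scope="session")
def small_annotation():
    return make_annotation(n_genes=30, genome_length=80_000, feature_fraction=0.1, seed=11)


@pytest.fixture(scope="session")
def annotation():
    return make_annotation(n_genes=120, genome_length=300_000, feature_fraction=0.1, seed=3)


@pytest.fixture(scope="session")
def planted_array(annotation):
    """Default planted tiling dataset shared by tiling/enrichment tests."""
    probes, truth = simulate_tiling_array(annotation, seed=4)
    return probes, truth


@pytest.fixture()
def clean_curve():
    params = GrowthParams(gamma=1.0, lag=2.0, amplitude=6.0, baseline=-6.6)
    return simulate_growth_curves(params, n_replicates=1, noise_sd=0.0, seed=0)[0], params


def null_probe_table(n_probes: int, n_rep: int, noise_sd: float, rng) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "position": np.arange(n_probes) * 50,
            "strand": np.where(np.arange(n_probes) % 2 == 0, "+", "-"),
        }
    )
    for j in range(n_rep):
        df[f"log2_ratio_rep{j + 1}"] = rng.normal(0.0, noise_sd, n_probes)
    return df
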