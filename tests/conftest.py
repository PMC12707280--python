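import numpy as np
import pandas as pd
import pytest

from germnet.matrices import CountMatrix
from germnet.simulate import DesignSpec, GeneratorParams, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A quick default-design dataset shared by read-only tests."""
    spec = DesignSpec(seed=7)
    params = GeneratorParams(
        n_plant_genes=120,
        n_microbial_genes=80,
        n_pathways=12,
        n_diffcorr_pairs=8,
        n_trait_features_plant=4,
        n_trait_features_microbe=4,
    )
    meta, plant, microbe, annotation, truth = simulate_dataset(spec, params)
    return {
        "meta": meta,
        "plant": plant,
        "microbe": microbe,
        "annotation": annotation,
        "truth": truth,
        "params": params,
    }


@pytest.fixture()
def toy_counts():
    data = pd.DataFrame(
        {
            "s1": [80, 80, 74],
            "s2": [80, 80, 74],
            "s3": [80, 80, 74],
            "s4": [80, 0, 74],
            "s5": [0, 0, 74],
        },
        index=["geneA", "geneB", "geneC"],
    )
    return CountMatrix(data=data, kind="plant_gene")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
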