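import numpy as np
import pandas as pd
import pytest

from fragstatis.datamodel import AbundanceDataset
from fragstatis.synthetic import GeneratorConfig, generate_dataset


def make_dataset(values, groups=None, stages=None, accessions=None,
                 met_class=None):
    """Small hand-built dataset; values is an (n, p) array (NaN = missing)."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    accessions = accessions or [f"A{i % 4 + 1}" for i in range(n)]
    groups = groups or ["D" if a in {"A1", "A2"} else "W" for a in accessions]
    stages = stages or [("G", "W", "R")[i % 3] for i in range(n)]
    samples = pd.DataFrame({
        "accession": accessions,
        "group": groups,
        "species": ["F_ananassa"] * n,
        "stage": stages,
        "replicate": [i // 3 + 1 for i in range(n)],
    }, index=pd.Index([f"s{i + 1}" for i in range(n)], name="sample_id"))
    met_class = met_class or ["primary"] * p
    mets = pd.DataFrame(
        {"met_class": met_class, "annotation": [""] * p},
        index=pd.Index([f"m{j + 1}" for j in range(p)], name="metabolite_id"))
    return AbundanceDataset(samples, mets,
                            pd.DataFrame(values, index=samples.index,
                                         columns=mets.index))


def quiet_config(**kw) -> GeneratorConfig:
    """Generator config with all planted effects and missingness off."""
    base = dict(n_planted_hubs=0, n_planted_biomarkers_primary=0,
                n_planted_biomarkers_secondary=0, missing_rate=0.0,
                n_high_missing_primary=0, n_high_missing_secondary=0)
    base.update(kw)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic dataset shared across tests."""
    return generate_dataset(GeneratorConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
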