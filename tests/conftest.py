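import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import odorforest as of
from odorforest import model as mod
from odorforest import preprocess as pp
from odorforest import synthetic as syn

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_study() -> syn.SyntheticDataset:
    """A small but complete synthetic study reused across test modules."""
    cfg = syn.PanelConfig(
        seed=1,
        n_molecules=40,
        n_replicated=4,
        n_subjects=5,
        n_attributes=6,
        n_descriptors=40,
        noise_sd=15.0,
    )
    return syn.generate(cfg)


@pytest.fixture(scope="session")
def small_aligned(small_study) -> of.AlignedData:
    return of.align(small_study.ratings, small_study.descriptors, small_study.names)


@pytest.fixture(scope="session")
def small_examples(small_aligned) -> pp.ExampleSet:
    return pp.build_examples(small_aligned.ratings)


@pytest.fixture(scope="session")
def small_scaled(small_aligned):
    scaler = pp.fit_scaler(small_aligned.descriptors)
    return pp.apply_scaler(small_aligned.descriptors, scaler)


@pytest.fixture
def tiny_spec() -> mod.LearnerSpec:
    return mod.LearnerSpec(n_trees=10, seed=3)


def make_ratings(
    n_molecules=4,
    n_subjects=2,
    attributes=("intensity", "pleasantness", "sweet"),
    seed=0,
    missing_fraction=0.0,
    dilutions=("1/10", "1/1,000"),
) -> of.RatingsTable:
    """Hand-rolled ratings fixture independent of the synthetic generator."""
    rng = np.random.default_rng(seed)
    rows = []
    for cid in range(201, 201 + n_molecules):
        for conc, dil in zip(("high", "low"), dilutions):
            for subject in range(1, n_subjects + 1):
                for attribute in attributes:
                    value = float(np.round(rng.uniform(0, 100), 3))
                    if missing_fraction and rng.random() < missing_fraction:
                        value = np.nan
                    rows.append(
                        {
                            "cid": cid,
                            "replicate": 0,
                            "concentration": conc,
                            "dilution": dil,
                            "subject": subject,
                            "attribute": attribute,
                            "value": value,
                        }
                    )
    return of.RatingsTable(pd.DataFrame(rows), tuple(attributes)).validate()
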