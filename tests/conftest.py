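import numpy as np
import pandas as pd
import pytest

import trisomod as tm


def small_config(seed: int = 0, **overrides) -> tm.SimulationConfig:
    """A fast desk-scale cohort used by most unit tests."""
    base = dict(
        n_genes=300, n_samples_t21=60, n_samples_d21=40, k_true=6,
        n_pathways=12, pathway_size_range=(10, 25), frac_aligned=1.0,
        sgm_indices=(0, 1), sgm_effect=1.0,
        noise_sd_expression=0.2, noise_sd_loadings=0.05,
        trait_plants=(("trait_a", 0, 2.0), ("trait_null", 0, 0.0)),
        corr_block_size=10, corr_rho=0.3,
        comorbidity_plants=(("com_a", 1, 0.0, 3.0),),
        seed=seed,
    )
    base.update(overrides)
    return tm.SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    return tm.generate_dataset(small_config(seed=4))


@pytest.fixture(scope="session")
def small_model(small_dataset):
    ds = small_dataset
    Xn = tm.zscore_rows(ds.expression)
    C_masked, _ = tm.mask_prior(ds.truth.C_true, 0.2, seed=1)
    return tm.fit(Xn, C_masked, k=ds.config.k_true, frac=0.7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_labels_scores(rng, n=40, p_case=0.4):
    labels = (rng.random(n) < p_case).astype(int)
    if labels.sum() == 0:
        labels[0] = 1
    if labels.sum() == n:
        labels[0] = 0
    return rng.normal(size=n), labels


@pytest.fixture(scope="session")
def tiny_activity_table():
    """Activities with one clear karyotype-shifted module and three nulls."""
    rng = np.random.default_rng(7)
    samples = [f"s{i}" for i in range(30)]
    kar = pd.Series(["T21"] * 18 + ["D21"] * 12, index=samples)
    B = pd.DataFrame(rng.normal(size=(4, 30)),
                     index=["LV1", "LV2", "LV3", "LV4"], columns=samples)
    B.loc["LV2", kar == "T21"] += 2.5
    return B, kar
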