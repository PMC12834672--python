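"""Shared fixtures: small synthetic datasets and fast sampler configs."""

import numpy as np
import pandas as pd
import pytest

from locscale.data import EXTENT_BINS, dataset_from_frame
from locscale.inference import McmcConfig


def make_meta_frame(n_studies=4, cases=3, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_studies):
        for j in range(cases):
            n_ij = int(rng.integers(10, 120))
            rows.append({
                "study_id": f"s{i}", "case_id": f"c{j}",
                "z": float(rng.normal(0.2, 0.4)),
                "n": n_ij, "var_z": 1.0 / (n_ij - 3),
                "log_grain": float(rng.normal(2.0, 2.0)),
                "extent_bin": EXTENT_BINS[int(rng.integers(len(EXTENT_BINS)))],
            })
    return pd.DataFrame(rows)


def make_fragment_frame(n_studies=4, frags=4, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_studies):
        for j in range(frags):
            rows.append({
                "study_id": f"s{i}", "fragment_id": f"f{j}",
                "richness": float(np.exp(rng.normal(2.0, 0.6))),
                "log_frag_size": float(rng.normal(0.0, 2.0)),
            })
    frame = pd.DataFrame(rows)
    frame["log_frag_size"] -= frame["log_frag_size"].mean()
    return frame


@pytest.fixture(scope="session")
def meta_toy():
    return dataset_from_frame(make_meta_frame(), "meta")


@pytest.fixture(scope="session")
def fragment_toy():
    return dataset_from_frame(make_fragment_frame(), "fragment", center_log_size=0.0)


@pytest.fixture(scope="session")
def fast_config():
    """Short, seeded sampler settings for unit-level fits."""
    return McmcConfig(chains=1, warmup=120, samples=150, seed=11,
                      adapt_target=0.85, max_treedepth=8)


@pytest.fixture(scope="session")
def two_chain_config():
    return McmcConfig(chains=2, warmup=150, samples=150, seed=11,
                      adapt_target=0.85, max_treedepth=8)
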