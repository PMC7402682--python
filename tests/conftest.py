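"""Shared fixtures: small synthetic datasets and reusable truth configs."""

import numpy as np
import pandas as pd
import pytest

import befmeta as b


@pytest.fixture(scope="session")
def default_truth():
    return b.TruthConfig(seed=11)


@pytest.fixture(scope="session")
def effects_dataset(default_truth):
    """A paper-scale synthetic effect table (~69 studies)."""
    return b.generate_effect_table(default_truth)


@pytest.fixture(scope="session")
def raw_dataset():
    """A small raw-study dataset exercising both designs and all metrics."""
    return b.generate_raw_studies(b.TruthConfig(n_studies=25, seed=7))


@pytest.fixture(scope="session")
def small_meta_table():
    """40 studies x 1-3 observations with known truth, for meta-model tests."""
    rng = np.random.default_rng(5)
    rows = []
    for s in range(40):
        u = rng.normal(0, 0.2)
        for o in range(rng.integers(1, 4)):
            n = int(rng.integers(6, 30))
            v = 1.0 / (n - 3)
            rows.append(
                {
                    "case_study_id": f"S{s}",
                    "z": -0.3 + u + rng.normal(0, np.sqrt(v)),
                    "var_z": v,
                    "x": rng.normal(),
                    "group": rng.choice(["a", "b"]),
                }
            )
    return pd.DataFrame(rows)


def null_truth(**kwargs):
    """A TruthConfig with every mean, slope and path set to zero."""
    zero = {"stressor": 0.0, "nutrient": 0.0}
    base = dict(
        mu_diversity=dict(zero),
        mu_abundance=dict(zero),
        beta_intensity=dict(zero),
        path_b=0.0,
        path_direct=0.0,
        tau_study=0.0,
        sigma_obs=0.0,
    )
    base.update(kwargs)
    return b.TruthConfig(**base)
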