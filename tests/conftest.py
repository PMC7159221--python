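"""Shared fixtures: small seeded synthetic datasets reused across tests."""

import numpy as np
import pandas as pd
import pytest

from readmit.synthetic_claims import (GeneratorConfig, default_config,
                                      generate_dataset)


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """~5k admissions over 30 hospitals; enough for distributional checks."""
    return default_config("ami", n_hospitals=30, seed=20240)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    hospitals, universe, table = generate_dataset(small_config)
    return small_config, hospitals, universe, table


@pytest.fixture(scope="session")
def tiny_records() -> pd.DataFrame:
    """Hand-sized record table with explicit code lists for oracle tests."""
    rng = np.random.default_rng(7)
    dx = [f"D{i:02d}" for i in range(12)]
    proc = [f"P{i:02d}" for i in range(6)]
    rows = []
    for i in range(200):
        sec = list(rng.choice(dx, size=rng.integers(0, 6), replace=False))
        pr = list(rng.choice(proc, size=rng.integers(0, 3), replace=False))
        rows.append({
            "patient_id": i,
            "hospital_id": int(rng.integers(0, 4)),
            "age": float(rng.normal(65, 10)),
            "female": int(rng.integers(0, 2)),
            "admission_month": int(rng.integers(1, 12)),
            "length_of_stay": int(rng.integers(1, 10)),
            "died": 0, "ama": 0, "transfer_out": 0,
            "principal_dx": str(rng.choice(dx)),
            "secondary_dx": sec,
            "procedures": pr,
            "readmit_30d": int(rng.integers(0, 2)),
            "planned_readmit": 0,
        })
    return pd.DataFrame(rows)
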