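import warnings

import numpy as np
import pytest

from betascape.core_io import OccurrenceMatrix, SiteTable
from betascape.synthetic_data import SyntheticConfig, generate_landscape, generate_occurrences

import pandas as pd


@pytest.fixture()
def toy_occurrences() -> OccurrenceMatrix:
    """Three sites, four species, hand-checkable overlaps."""
    inc = np.array(
        [
            [1, 1, 1, 0],
            [1, 1, 0, 1],
            [0, 0, 1, 1],
        ]
    )
    return OccurrenceMatrix(("s1", "s2", "s3"), ("a", "b", "c", "d"), inc)


def _site_frame(n: int, rng: np.random.Generator) -> pd.DataFrame:
    lat = rng.uniform(36, 70, n)
    lon = rng.uniform(-10, 60, n)
    return pd.DataFrame(
        {
            "Area": rng.lognormal(11, 0.5, n),
            "Long": lon, "Long_min": lon - 1, "Long_max": lon + 1, "Long_ran": 2.0,
            "Lat": lat, "Lat_min": lat - 1, "Lat_max": lat + 1, "Lat_ran": 2.0,
            "Alt": rng.gamma(2, 200, n), "Alt_ran": rng.gamma(2, 100, n),
            "T_ann": 16 - 0.55 * (lat - 36) + rng.normal(0, 1, n),
            "T_ran": rng.gamma(2, 1, n),
            "T_max": 26 - 0.55 * (lat - 36), "T_min": 6 - 0.55 * (lat - 36),
            "P_ann": rng.gamma(4, 180, n), "P_ran": rng.gamma(2, 50, n),
            "P_dri": rng.gamma(2, 30, n), "P_drn": rng.gamma(2, 15, n),
        },
        index=[f"U{i:02d}" for i in range(n)],
    )


@pytest.fixture()
def random_site_table() -> SiteTable:
    return SiteTable(_site_frame(20, np.random.default_rng(7)))


def make_site_table(n: int, seed: int) -> SiteTable:
    return SiteTable(_site_frame(n, np.random.default_rng(seed)))


@pytest.fixture(scope="session")
def default_synthetic():
    """One default-configuration synthetic dataset, shared across tests."""
    config = SyntheticConfig(seed=11)
    landscape = generate_landscape(config)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        occ, truth = generate_occurrences(config, landscape)
    return config, landscape, occ, truth


def random_binary_matrix(rng: np.random.Generator, max_sites=12, max_species=30):
    """A random occurrence matrix with no empty sites (for beta oracles)."""
    n = rng.integers(3, max_sites + 1)
    m = rng.integers(4, max_species + 1)
    while True:
        inc = (rng.uniform(size=(n, m)) < rng.uniform(0.2, 0.8)).astype(np.int8)
        if (inc.sum(axis=1) > 0).all():
            break
    return OccurrenceMatrix(
        tuple(f"s{i}" for i in range(n)), tuple(f"x{j}" for j in range(m)), inc
    )
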