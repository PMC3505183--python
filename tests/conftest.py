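import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import dgekit as dk

settings.register_profile("stable", derandomize=True, deadline=None)
settings.load_profile("stable")
from dgekit.types import ExpressionMatrix


@pytest.fixture(scope="session")
def small_ref():
    return dk.generate_reference(50, length_range=(200, 400), spacer=100, seed=1)


@pytest.fixture(scope="session")
def small_index(small_ref):
    return dk.build_tag_index(small_ref)


@pytest.fixture(scope="session")
def noisefree_library(small_ref):
    profile = dk.uniform_profile(small_ref)
    lib = dk.simulate_library(
        small_ref, profile, depth=50_000,
        error_rate=0.0, adaptor_rate=0.0, singleton_rate=0.0, seed=3,
    )
    return dk.extract_clean_tags(lib)


def matrix_from_counts(count_cols: dict[str, list[int]], totals: dict[str, int], genes=None):
    genes = genes or [f"g{i}" for i in range(len(next(iter(count_cols.values()))))]
    counts = pd.DataFrame(count_cols, index=genes)
    return ExpressionMatrix(counts=counts, library_totals=totals)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
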