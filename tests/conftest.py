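"""Shared desk-scale fixtures: a small synthetic bundle with planted
rescue pairs, generated once per session."""

import pytest

from sr_rescue import synthetic_data as sd


@pytest.fixture(scope="session")
def small_truth():
    return sd.default_truth(n_du=5, n_dd=2, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_truth):
    cohort, states = sd.generate_cohort(small_truth, n_samples=800, n_genes=60)
    return cohort, states


@pytest.fixture(scope="session")
def small_panel(small_truth):
    return sd.generate_screen_panel(small_truth, n_cell_lines=100, n_genes=60)


@pytest.fixture(scope="session")
def small_profiles(small_truth):
    return sd.generate_phylo_profiles(small_truth, n_genes=60)
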