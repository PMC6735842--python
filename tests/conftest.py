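import numpy as np
import pytest

from seedspan.trait_table import (
    build_analysis_matrix,
    load_study_fixture,
    packaged_node_ages_path,
)
from seedspan.tree import bladj_adjust, build_taxonomy_tree, load_node_ages, phylo_covariance


@pytest.fixture(scope="session")
def fixture_table():
    return load_study_fixture()


@pytest.fixture(scope="session")
def fixture_frame(fixture_table):
    return fixture_table.to_frame()


@pytest.fixture(scope="session")
def fixture_matrix(fixture_table):
    return build_analysis_matrix(fixture_table)


@pytest.fixture(scope="session")
def fixture_tree(fixture_table):
    tree = build_taxonomy_tree(fixture_table.records)
    return bladj_adjust(tree, load_node_ages(packaged_node_ages_path()))


@pytest.fixture(scope="session")
def fixture_cov(fixture_tree):
    return phylo_covariance(fixture_tree)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
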