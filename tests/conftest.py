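import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings
from skbio import TreeNode

from ecoassembly.io import CommunityTable, Phylogeny, SampleFrame

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

SMALL_NEWICK = "((A:1,B:1):1,C:2);"
FIVE_TAXON_NEWICK = "((A:0.3,B:0.4):0.5,(C:0.2,(D:0.6,E:0.1):0.3):0.4);"


@pytest.fixture
def small_tree():
    return Phylogeny(TreeNode.read([SMALL_NEWICK]))


@pytest.fixture
def five_taxon_tree():
    return Phylogeny(TreeNode.read([FIVE_TAXON_NEWICK]))


@pytest.fixture
def counts_table():
    data = pd.DataFrame(
        [[5, 3, 0, 2, 0],
         [0, 8, 1, 0, 1],
         [2, 2, 2, 2, 2],
         [9, 0, 0, 1, 4]],
        index=["s1", "s2", "s3", "s4"], columns=list("ABCDE"))
    return CommunityTable(data, kind="counts")


@pytest.fixture
def sample_frame():
    rng = np.random.default_rng(0)
    data = pd.DataFrame({
        "plot_id": [1, 1, 2, 2],
        "plot_type": ["monoculture", "monoculture", "mixed", "mixed"],
        "host_species": ["focal_tree"] * 4,
        "x": [1.0, 5.0, 40.0, 44.0],
        "y": [2.0, 20.0, 8.0, 25.0],
        "pH": [5.1, 5.4, 6.0, 6.2],
        "water_content": [30.0, 32.0, 41.0, 39.0],
    }, index=["s1", "s2", "s3", "s4"])
    return SampleFrame(data, ("pH", "water_content"))


@pytest.fixture(scope="session")
def study_dataset():
    """Survey-shaped fixture: 64 samples / 8 plots, 3 shallow, 16 chemistry."""
    from ecoassembly.simulate import simulate_study_dataset
    return simulate_study_dataset(seed=0)
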