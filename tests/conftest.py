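import numpy as np
import pandas as pd
import pytest

from malonmap.io_formats import SiteIntensityTable
from malonmap.synthetic_data import SimulationConfig, simulate


@pytest.fixture(scope="session")
def small_bundle():
    """A compact simulated experiment shared across read-only tests."""
    return simulate(SimulationConfig(seed=11, n_proteins=60, n_sites=300))


@pytest.fixture()
def tiny_site_table():
    """Four sites x four samples (C1, C2, SA1, SA2), one missing cell."""
    samples = ["C1", "C2", "SA1", "SA2"]
    sites = pd.DataFrame(
        {
            "protein_id": ["p1", "p1", "p2", "p3"],
            "position": [65, 364, 10, 5],
            "residue": ["K"] * 4,
            "localization_prob": [0.99, 0.9, 0.8, 1.0],
        },
        index=pd.Index(["p1_K65", "p1_K364", "p2_K10", "p3_K5"], name="site_id"),
    )
    inten = pd.DataFrame(
        [
            [10.0, 20.0, 30.0, 40.0],
            [5.0, 5.0, 5.0, 5.0],
            [8.0, np.nan, 24.0, 16.0],
            [100.0, 110.0, 50.0, 55.0],
        ],
        index=sites.index,
        columns=samples,
    )
    groups = {"C1": "C", "C2": "C", "SA1": "SA", "SA2": "SA"}
    return SiteIntensityTable(sites=sites, intensities=inten, sample_groups=groups)


def write_tsv(path, text):
    path.write_text(text.replace(" | ", "\t"))
    return path
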