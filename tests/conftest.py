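import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ptxmap import simdata
from ptxmap.matrix import SEG_MATERNAL, GenotypeMatrix

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def toy_matrix(calls, seg_type=SEG_MATERNAL, contig="ctg1", positions=None,
               ids=None, ref="A", alt="C"):
    """Small GenotypeMatrix from an int list-of-lists."""
    calls = np.asarray(calls, dtype=np.int8)
    m, n = calls.shape
    if positions is None:
        positions = [100 * (i + 1) for i in range(m)]
    if ids is None:
        ids = [f"m{i}" for i in range(m)]
    markers = pd.DataFrame(
        {
            "contig": [contig] * m,
            "pos": positions,
            "ref": [ref] * m,
            "alt": [alt] * m,
            "seg_type": [seg_type] * m,
        },
        index=pd.Index(ids, name="marker_id"),
    )
    return GenotypeMatrix(markers, calls, [f"P{j + 1:03d}" for j in range(n)])


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free dual-view simulation: 3 chromosomes, 6 markers/parent."""
    spec = simdata.ParentSpec.regular(
        n_chromosomes=3, markers_per_parent=6, interval_cm=2.5, seed=7
    )
    return simdata.simulate_dataset(spec, n_progeny=150, seed=7)


@pytest.fixture
def toy():
    return toy_matrix
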