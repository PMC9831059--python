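import numpy as np
import pytest

from isoswitch.core_data import TimeCourseMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_matrix(values, gene_map, time_points=None, n_replicates=1, transcript_ids=None):
    values = np.asarray(values, dtype=float)
    n_samples = values.shape[1]
    if time_points is None:
        assert n_samples % n_replicates == 0
        time_points = [f"t{i}" for i in range(n_samples // n_replicates)]
    if transcript_ids is None:
        transcript_ids = list(gene_map.keys())
    return TimeCourseMatrix(
        values=values,
        transcript_ids=transcript_ids,
        time_points=time_points,
        n_replicates=n_replicates,
        gene_map=gene_map,
    )


@pytest.fixture
def two_isoform_switch():
    """A clean two-isoform gene that flips between t1 and t2 (R=2)."""
    # time-major, replicate-minor; T=4, R=2
    values = np.array(
        [
            [70, 72, 68, 71, 30, 29, 28, 31],
            [30, 28, 32, 29, 70, 71, 72, 69],
        ],
        dtype=float,
    )
    return make_matrix(values, {"g1.t1": "g1", "g1.t2": "g1"}, n_replicates=2)
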