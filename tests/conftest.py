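import pytest

from branchflow.swc_io import Reconstruction, SwcSample


def make_rec(rows, cell_id="cell", label=None):
    """Reconstruction from (id, type, x, y, z, radius, parent) tuples."""
    return Reconstruction(
        samples=[SwcSample(*r) for r in rows], cell_id=cell_id, label=label
    )


@pytest.fixture
def chain_rec():
    """Unbranched 10-sample dendrite chain along z, soma-rooted."""
    rows = [(1, 1, 0, 0, -1.0, 2.0, -1)]
    rows += [(i, 3, 0, 0, float(i - 2), 0.5, i - 1) for i in range(2, 12)]
    return make_rec(rows)


@pytest.fixture
def y_rec():
    """Y-shape: 3-sample root chain whose last sample has two 2-sample children."""
    rows = [
        (1, 3, 0, 0, 0.0, 1.0, -1),
        (2, 3, 0, 0, 1.0, 1.0, 1),
        (3, 3, 0, 0, 2.0, 1.0, 2),
        (4, 3, 1.0, 0, 3.0, 0.8, 3),
        (5, 3, 2.0, 0, 4.0, 0.8, 4),
        (6, 3, -1.0, 0, 3.0, 0.6, 3),
        (7, 3, -2.0, 0, 4.0, 0.6, 6),
    ]
    return make_rec(rows)
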