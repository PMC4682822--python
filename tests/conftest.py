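import numpy as np
import pytest

from wireopt import (
    ConnectivityData,
    NeuronTable,
    NormSpec,
    PlacementProblem,
    SynthConfig,
    WeightScheme,
    build_weights,
    generate_instance,
)

POSITIONS_TSV = """neuron_id\tclass\tx_mm\ty_mm
SENS1\tsensory\t0.05\t0.05
MOT1\tmotor\t0.1\t0.02
SENS2\tsensory\t1.1\t0.05
MOT2\tmotor\t1.15\t0.03
INT1\tinter\t0.5\t0.04
INT2\tinter\t0.6\t0.06
"""

EDGES_CSV = """pre,post,type,count
INT1,SENS1,chem,2
INT1,MOT1,chem,1
MOT1,INT1,chem,1
INT2,MOT2,chem,3
SENS2,INT2,chem,1
INT1,INT2,gap,2
SENS1,MOT1,chem,1
"""


@pytest.fixture
def toy_files(tmp_path):
    pos = tmp_path / "positions.tsv"
    edg = tmp_path / "edges.csv"
    pos.write_text(POSITIONS_TSV)
    edg.write_text(EDGES_CSV)
    return pos, edg


@pytest.fixture
def toy_instance(toy_files):
    from wireopt import read_edges, read_positions

    table = read_positions(toy_files[0])
    conn = read_edges(toy_files[1], table)
    return table, conn


@pytest.fixture(scope="session")
def worm_instance():
    """Small worm-like synthetic instance shared across tests."""
    cfg = SynthConfig(
        n_anchors_head=40, n_anchors_tail=30, n_anchors_cord=15, n_free=25,
        decay_scale=0.15, seed=11,
    )
    return generate_instance(cfg)


def make_problem(weights, fixed, coords, spec, **kw):
    return PlacementProblem(
        np.asarray(weights, float),
        np.asarray(fixed, bool),
        np.asarray(coords, float),
        spec,
        **kw,
    )


@pytest.fixture
def single_free_two_anchors():
    """One free node pulled by anchors at (0,0) w=1 and (3,0) w=3."""
    W = np.zeros((3, 3))
    W[2, 0] = 1.0
    W[2, 1] = 3.0
    coords = np.array([[0.0, 0.0], [3.0, 0.0], [1.0, 1.0]])
    fixed = np.array([True, True, False])
    return W, fixed, coords
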