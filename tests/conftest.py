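import numpy as np
import pytest

from lmp3d.fixtures import (
    FixtureSpec,
    methane,
    planar_ring,
    random_walk_chain,
    write_fixture,
)
from lmp3d.lammps_io import parse_data, parse_dump
from lmp3d.molecular_model import build_topology, make_snapshot, unwrap_frame


def snapshot_from_template(template, charges=None, timestep=0):
    """Build a MoleculeSnapshot directly from a fixture template."""
    spec = FixtureSpec(template=template, copies=1, frames=1, rigid_motion=False)
    if charges is not None:
        spec.charge_pattern = list(charges)
    import tempfile, os

    d = tempfile.mkdtemp()
    truth = write_fixture(spec, os.path.join(d, "f.data"), os.path.join(d, "f.dump"))
    data = parse_data(os.path.join(d, "f.data"))
    topo = build_topology(data)
    frames = parse_dump(os.path.join(d, "f.dump"))
    coords = unwrap_frame(frames[0], topo)[1]
    return make_snapshot(topo.molecules[1], timestep, coords)


@pytest.fixture
def methane_snapshot():
    return snapshot_from_template(methane())


@pytest.fixture
def chain10_snapshot():
    """10-atom seeded random-walk carbon chain with alternating charges."""
    return snapshot_from_template(
        random_walk_chain(10, 1.54, seed=42),
        charges=[0.3 * (-1) ** k for k in range(10)],
    )


@pytest.fixture
def chain20_snapshot():
    return snapshot_from_template(
        random_walk_chain(20, 1.54, seed=7),
        charges=[0.25 * (-1) ** k for k in range(20)],
    )


@pytest.fixture
def ring_snapshot():
    return snapshot_from_template(planar_ring(6))


@pytest.fixture
def fixture_pair(tmp_path):
    """Written 2-molecule methane fixture: (data path, dump path, truth)."""
    spec = FixtureSpec(
        template=methane(),
        copies=2,
        frames=3,
        seed=11,
        charge_pattern=[-0.4, 0.1, 0.1, 0.1, 0.1],
    )
    data_path = tmp_path / "sys.data"
    dump_path = tmp_path / "sys.lammpstrj"
    truth = write_fixture(spec, data_path, dump_path)
    return str(data_path), str(dump_path), truth


def rigid_variants(snapshot, seed=123):
    """The same snapshot after a seeded rigid rotation + translation."""
    from lmp3d.fixtures import perturb

    moved = perturb(snapshot.coords, seed)
    return make_snapshot(snapshot.topology, snapshot.timestep, moved)
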