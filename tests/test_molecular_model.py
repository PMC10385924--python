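"""Element inference, topology construction, unwrapping and geometry."""

import numpy as np
import pytest

from lmp3d.errors import DisconnectedMolecule, UnknownMass
from lmp3d.fixtures import FixtureSpec, generate, random_walk_chain, write_fixture
from lmp3d.lammps_io import parse_data, parse_dump
from lmp3d.molecular_model import (
    build_topology,
    geometry_matrices,
    make_snapshot,
    unwrap_frame,
)
from lmp3d.properties import PROPERTY_TABLE, infer_element


@pytest.mark.parametrize(
    "mass,expected",
    [
        (12.011, "C"),
        (1.008, "H"),
        (15.999, "O"),
        (15.035, "CH3"),
        (14.027, "CH2"),
        (13.019, "CH"),
        (16.043, "CH4"),
        (12.2, "C"),
    ],
)
def test_infer_element_maps_masses(mass, expected):
    assert infer_element(mass) == expected


def test_infer_element_rejects_unknown_mass():
    with pytest.raises(UnknownMass):
        infer_element(6.5)


def test_ua_pseudo_elements_take_carbon_properties_but_own_mass():
    ch3 = PROPERTY_TABLE["CH3"]
    carbon = PROPERTY_TABLE["C"]
    assert ch3.mass == 15.035
    assert ch3.vdw_radius == carbon.vdw_radius
    assert ch3.polarizability == carbon.polarizability


def _floyd_warshall(n, edges):
    """Independent all-pairs oracle for topological distances."""
    inf = 10**9
    d = [[0 if i == j else inf for j in range(n)] for i in range(n)]
    for i, j in edges:
        d[i][j] = d[j][i] = 1
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    return d


def test_topological_distances_match_floyd_warshall(tmp_path):
    spec = FixtureSpec(template=random_walk_chain(25, 1.54, seed=1))
    truth = write_fixture(spec, tmp_path / "c.data", tmp_path / "c.dump")
    topo = build_topology(parse_data(tmp_path / "c.data"))
    mol = topo.molecules[1]
    edges = [(i, j) for i, j in mol.bonds]
    oracle = _floyd_warshall(mol.n_atoms, edges)
    np.testing.assert_array_equal(mol.topo_dist, np.array(oracle))


def test_path_graph_end_to_end_topological_distance(tmp_path):
    spec = FixtureSpec(template=random_walk_chain(4, 1.54, seed=2))
    write_fixture(spec, tmp_path / "p.data", tmp_path / "p.dump")
    topo = build_topology(parse_data(tmp_path / "p.data"))
    assert topo.molecules[1].topo_dist[0, 3] == 3


def test_cross_molecule_bond_is_rejected(tmp_path):
    spec = FixtureSpec(template=random_walk_chain(4, 1.54, seed=2), copies=2)
    data_text, _, _ = generate(spec)
    # add a bond joining molecule 1 (atom 1) to molecule 2 (atom 5)
    lines = data_text.split("\n")
    count_idx = next(i for i, l in enumerate(lines) if l.endswith(" bonds"))
    n_bonds = int(lines[count_idx].split()[0])
    lines[count_idx] = f"{n_bonds + 1} bonds"
    last_bond = max(i for i, l in enumerate(lines) if l.strip() and l.split()[0].isdigit())
    lines.insert(last_bond + 1, f"{n_bonds + 1} 1 1 5")
    path = tmp_path / "x.data"
    path.write_text("\n".join(lines))
    with pytest.raises(DisconnectedMolecule):
        build_topology(parse_data(path))


def test_minimum_image_unwrap_analytic_case(tmp_path):
    """Two bonded atoms at x = 0.5 and 9.8 in a 10 A box sit 0.7 A apart."""
    data = """two atoms

2 atoms
1 bonds
1 atom types
1 bond types

0.0 10.0 xlo xhi
0.0 10.0 ylo yhi
0.0 10.0 zlo zhi

Masses

1 12.011

Atoms  # full

1 1 1 0.0 0.5 5.0 5.0
2 1 1 0.0 9.8 5.0 5.0

Bonds

1 1 1 2
"""
    dump = """ITEM: TIMESTEP
0
ITEM: NUMBER OF ATOMS
2
ITEM: BOX BOUNDS pp pp pp
0.0 10.0
0.0 10.0
0.0 10.0
ITEM: ATOMS id mol type x y z
1 1 1 0.5 5.0 5.0
2 1 1 9.8 5.0 5.0
"""
    (tmp_path / "t.data").write_text(data)
    (tmp_path / "t.dump").write_text(dump)
    topo = build_topology(parse_data(tmp_path / "t.data"))
    frame = parse_dump(tmp_path / "t.dump")[0]
    coords = unwrap_frame(frame, topo)[1]
    assert np.linalg.norm(coords[0] - coords[1]) == pytest.approx(0.7, abs=1e-12)


def test_unwrapped_input_passes_through(tmp_path):
    spec = FixtureSpec(
        template=random_walk_chain(8, 1.54, seed=4), frames=2, wrap=False
    )
    truth = write_fixture(spec, tmp_path / "u.data", tmp_path / "u.dump")
    topo = build_topology(parse_data(tmp_path / "u.data"))
    frames = parse_dump(tmp_path / "u.dump")
    for f, frame in enumerate(frames):
        out = unwrap_frame(frame, topo)
        np.testing.assert_allclose(out[1], truth.frames[f][1], atol=1e-7)


def test_wrapped_chain_recovers_ground_truth_bond_lengths(tmp_path):
    """A 20-atom chain wrapped across a 15 A box unwraps to the exact
    generator bond lengths (whole-molecule translation allowed)."""
    spec = FixtureSpec(
        template=random_walk_chain(20, 1.54, seed=8),
        box=(15.0, 15.0, 15.0),
        frames=2,
        wrap=True,
    )
    truth = write_fixture(spec, tmp_path / "w.data", tmp_path / "w.dump")
    topo = build_topology(parse_data(tmp_path / "w.data"))
    frames = parse_dump(tmp_path / "w.dump")
    mol = topo.molecules[1]
    for f, frame in enumerate(frames):
        coords = unwrap_frame(frame, topo)[1]
        ref = truth.frames[f][1]
        for i, j in mol.bonds:
            got = np.linalg.norm(coords[i] - coords[j])
            want = np.linalg.norm(ref[i] - ref[j])
            assert got == pytest.approx(want, abs=1e-9)
        # all pairwise distances agree, not just bonds
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(pdist(coords), pdist(ref), atol=1e-9)


def test_unwrap_is_idempotent(tmp_path):
    spec = FixtureSpec(
        template=random_walk_chain(10, 1.54, seed=5), wrap=True, box=(20.0, 20.0, 20.0)
    )
    write_fixture(spec, tmp_path / "i.data", tmp_path / "i.dump")
    topo = build_topology(parse_data(tmp_path / "i.data"))
    frame = parse_dump(tmp_path / "i.dump")[0]
    once = unwrap_frame(frame, topo)[1]
    frame.coords = np.array(once)
    frame.coord_kind = "unwrapped"
    twice = unwrap_frame(frame, topo)[1]
    np.testing.assert_array_equal(once, twice)


def test_geometry_matrices_against_brute_force():
    rng = np.random.default_rng(0)
    coords = rng.uniform(-5, 5, size=(10, 3))
    dist, centered = geometry_matrices(coords)
    for i in range(10):
        for j in range(10):
            want = np.sqrt(((coords[i] - coords[j]) ** 2).sum())
            assert abs(dist[i, j] - want) < 1e-12
    np.testing.assert_allclose(centered.mean(axis=0), 0.0, atol=1e-9)


def test_geometry_matrices_345_triangle_and_single_atom():
    dist, _ = geometry_matrices(np.array([[0.0, 0.0, 0.0], [3.0, 4.0, 0.0]]))
    assert dist[0, 1] == pytest.approx(5.0)
    dist1, centered1 = geometry_matrices(np.array([[2.0, 3.0, 4.0]]))
    assert dist1.shape == (1, 1) and dist1[0, 0] == 0.0
    np.testing.assert_allclose(centered1, 0.0)
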