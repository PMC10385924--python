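"""Set-2 geometric descriptors vs closed forms and numeric oracles."""

import math

import numpy as np
import pytest

from lmp3d.desc_geometric import (
    NAMES,
    chain_measures,
    dipole,
    geometric,
    gravitation,
    inertia_and_gyration,
    molvolume,
    pbf,
    shadow_indices,
)
from lmp3d.fixtures import ideal_alkane, planar_ring, random_walk_chain
from lmp3d.molecular_model import make_snapshot

from conftest import rigid_variants, snapshot_from_template


def test_dipole_closed_form():
    """+0.5/-0.5 e, 1 A apart, equal masses -> 0.5 e*A = 2.4016 D."""
    snap = snapshot_from_template(ideal_alkane(2), charges=[0.5, -0.5])
    coords = np.array([[1.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
    snap = make_snapshot(snap.topology, 0, coords)
    assert dipole(snap) == pytest.approx(0.5 * 4.8032)


def test_dipole_vanishes_for_zero_and_mirrored_charges():
    snap = snapshot_from_template(ideal_alkane(2), charges=[0.0, 0.0])
    assert dipole(snap) == 0.0
    snap4 = snapshot_from_template(ideal_alkane(4), charges=[0.3, -0.3, -0.3, 0.3])
    coords = np.array(
        [[-2.0, 0, 0], [-1.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]], dtype=float
    )
    snap4 = make_snapshot(snap4.topology, 0, coords)
    assert dipole(snap4) == pytest.approx(0.0, abs=1e-12)


def test_rg_of_symmetric_dumbbell_is_one():
    snap = snapshot_from_template(ideal_alkane(2))
    coords = np.array([[1.0, 0.0, 0.0], [-1.0, 0.0, 0.0]])
    snap = make_snapshot(snap.topology, 0, coords)
    vals = inertia_and_gyration(snap)
    assert vals["Rg"] == pytest.approx(1.0)
    assert vals["acylindricity"] == pytest.approx(0.0, abs=1e-12)


def test_rod_has_zero_acylindricity_and_square_is_plane_degenerate():
    rod = snapshot_from_template(ideal_alkane(4))
    coords = np.array([[float(i), 0.0, 0.0] for i in range(4)])
    rod = make_snapshot(rod.topology, 0, coords)
    assert inertia_and_gyration(rod)["acylindricity"] == pytest.approx(0.0, abs=1e-12)
    # square: the two in-plane gyration eigenvalues coincide
    sq = snapshot_from_template(planar_ring(4))
    m = sq.topology.masses
    com = (m[:, None] * sq.coords).sum(axis=0) / m.sum()
    d = sq.coords - com
    lam = np.sort(np.linalg.eigvalsh((m[:, None, None] * d[:, :, None] * d[:, None, :]).sum(0) / m.sum()))
    assert lam[1] == pytest.approx(lam[2], abs=1e-9)
    assert lam[0] == pytest.approx(0.0, abs=1e-12)


def test_gyration_eigenvalues_match_brute_force(chain10_snapshot):
    m = chain10_snapshot.topology.masses
    coords = chain10_snapshot.coords
    com = (m[:, None] * coords).sum(axis=0) / m.sum()
    t = np.zeros((3, 3))
    for k in range(len(m)):
        d = coords[k] - com
        t += m[k] * np.outer(d, d)
    t /= m.sum()
    lam = np.sort(np.linalg.eigvalsh(t))
    vals = inertia_and_gyration(chain10_snapshot)
    assert vals["Rg"] == pytest.approx(math.sqrt(lam.sum()), abs=1e-10)
    assert vals["asphericity"] == pytest.approx(
        lam[2] - (lam[0] + lam[1]) / 2, abs=1e-10
    )


def test_gravitation_hand_sums():
    snap = snapshot_from_template(ideal_alkane(2))
    coords = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
    snap = make_snapshot(snap.topology, 0, coords)
    m = snap.topology.masses
    g1, g2 = gravitation(snap)
    assert g1 == pytest.approx(m[0] * m[1] / 4.0)
    assert g2 == pytest.approx(g1)


def test_gravitation_three_atom_chain_nonbonded_pair():
    snap = snapshot_from_template(ideal_alkane(3))
    g1, g2 = gravitation(snap)
    m = snap.topology.masses
    r13 = snap.distances[0, 2]
    assert g1 - g2 == pytest.approx(m[0] * m[2] / r13**2, abs=1e-9)


def test_molvolume_single_sphere_and_disjoint_union():
    snap1 = snapshot_from_template(ideal_alkane(2))
    one = make_snapshot(snap1.topology, 0, np.array([[0.0, 0, 0], [20.0, 0, 0]]))
    analytic = 4.0 / 3.0 * math.pi * 1.7**3
    vol = molvolume(one)
    assert vol == pytest.approx(2 * analytic, rel=0.02)
    coincident = make_snapshot(snap1.topology, 0, np.zeros((2, 3)))
    assert molvolume(coincident) == pytest.approx(analytic, rel=0.02)


def test_molvolume_grows_with_radius(chain10_snapshot):
    base = molvolume(chain10_snapshot)
    finer = molvolume(chain10_snapshot, grid=0.25)
    assert finer == pytest.approx(base, rel=0.05)  # grid robustness
    # a superset of spheres cannot shrink the union
    assert base > 0


def test_shadow_single_atom_analytic():
    snap = snapshot_from_template(ideal_alkane(2))
    # collapse to effectively one carbon: coincident atoms
    snap = make_snapshot(snap.topology, 0, np.zeros((2, 3)))
    s = shadow_indices(snap)
    disk = math.pi * 1.7**2
    for k in (1, 2, 3):
        assert s[f"S{k}"] == pytest.approx(disk, rel=0.02)
    for k in (4, 5, 6):
        assert s[f"S{k}"] == pytest.approx(math.pi / 4, rel=0.02)


def test_shadow_invariant_under_rotation(chain10_snapshot):
    s0 = shadow_indices(chain10_snapshot)
    s1 = shadow_indices(rigid_variants(chain10_snapshot))
    for k in range(1, 7):
        assert s1[f"S{k}"] == pytest.approx(s0[f"S{k}"], rel=0.02)


def test_pbf_planar_and_degenerate_cases(ring_snapshot):
    assert pbf(ring_snapshot) == pytest.approx(0.0, abs=1e-9)
    two = snapshot_from_template(ideal_alkane(2))
    assert pbf(two) == 0.0


def test_pbf_matches_least_squares_plane_oracle():
    """PBF equals the mean |distance| to the plane minimising the summed
    squared distance, found by brute-force search over orientations."""
    rng = np.random.default_rng(17)
    coords = rng.uniform(-2, 2, size=(8, 3))
    coords[:, 2] *= 0.3  # flattened so the best plane is unique
    snap = snapshot_from_template(random_walk_chain(8, 1.54, seed=1))
    snap = make_snapshot(snap.topology, 0, coords)
    got = pbf(snap)
    centered = coords - coords.mean(axis=0)

    def sumsq(angles):
        th, ph = angles
        nvec = np.array(
            [math.sin(th) * math.cos(ph), math.sin(th) * math.sin(ph), math.cos(th)]
        )
        return float(((centered @ nvec) ** 2).sum())

    from scipy.optimize import minimize

    best_sq, best_angles = math.inf, None
    for th in np.linspace(0.1, math.pi - 0.1, 20):
        for ph in np.linspace(0, 2 * math.pi, 40):
            res = minimize(sumsq, [th, ph], method="Nelder-Mead")
            if res.fun < best_sq:
                best_sq, best_angles = res.fun, res.x
    th, ph = best_angles
    nvec = np.array(
        [math.sin(th) * math.cos(ph), math.sin(th) * math.sin(ph), math.cos(th)]
    )
    best_abs = float(np.abs(centered @ nvec).mean())
    assert got == pytest.approx(best_abs, abs=1e-6)


def test_straight_chain_measures():
    snap = snapshot_from_template(ideal_alkane(5, bond=1.0))
    coords = np.array([[float(i), 0.0, 0.0] for i in range(5)])
    snap = make_snapshot(snap.topology, 0, coords)
    vals = chain_measures(snap)
    assert vals["Ree"] == pytest.approx(4.0)
    assert vals["Lcontour"] == pytest.approx(4.0)
    assert vals["lk"] == pytest.approx(4.0)
    for k in range(1, 5):
        assert vals[f"phi{k}"] == pytest.approx(1.0)
    for k in range(5, 11):
        assert vals[f"phi{k}"] == 0.0


def test_folded_chain_has_zero_kuhn_length():
    snap = snapshot_from_template(ideal_alkane(3, bond=1.0))
    coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 0, 0]])
    snap = make_snapshot(snap.topology, 0, coords)
    vals = chain_measures(snap)
    assert vals["Ree"] == 0.0
    assert vals["lk"] == 0.0


def test_phi4_matches_windowed_ratio_oracle(chain20_snapshot):
    vals = chain_measures(chain20_snapshot)
    coords = chain20_snapshot.coords
    path = list(range(20))  # backbone of a path graph is the chain itself
    seg = [math.dist(coords[i], coords[i + 1]) for i in range(19)]
    k = 4
    ratios = [
        math.dist(coords[i], coords[i + k]) / sum(seg[i : i + k])
        for i in range(20 - k)
    ]
    assert vals["phi4"] == pytest.approx(sum(ratios) / len(ratios), abs=1e-12)
    assert all(0 < vals[f"phi{j}"] <= 1 + 1e-12 for j in range(1, 11))


def test_full_block_invariance_and_order(chain10_snapshot):
    base = geometric(chain10_snapshot)
    assert tuple(base.keys()) == NAMES
    moved = geometric(rigid_variants(chain10_snapshot))
    for name in NAMES:
        if name in ("molvolume",) or name.startswith("S"):
            assert moved[name] == pytest.approx(base[name], rel=0.02), name
        else:
            assert moved[name] == pytest.approx(base[name], abs=1e-7), name
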