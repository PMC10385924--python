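"""Set 2 — shape and size descriptors.

Dipole moment, principal moments of inertia, gyration-tensor shape
measures, gravitation indices, grid-based molecular volume and shadow
areas, plane-of-best-fit score, and backbone chain-folding measures
(end-to-end distance, contour length, Kuhn length, folding profiles
phi1..phi10).
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from .molecular_model import MoleculeSnapshot

#: e*A -> Debye.
DEBYE_PER_E_ANGSTROM = 4.8032
#: Cubic grid spacing for the vdW-volume estimate, A.
VOLUME_GRID = 0.2
#: 2D grid spacing for shadow projections, A.
SHADOW_GRID = 0.1

NAMES = (
    ("dipole_debye",)
    + ("I1", "I2", "I3", "I1/I2", "I1/I3", "I2/I3", "inertialShapeFactor")
    + ("Rg", "asphericity", "acylindricity", "kappa2")
    + ("grav1", "grav2", "molvolume")
    + tuple(f"S{k}" for k in range(1, 7))
    + ("PBF", "span", "diameter3D_geo", "Ree", "Lcontour", "lk")
    + tuple(f"phi{k}" for k in range(1, 11))
)


def dipole(snapshot: MoleculeSnapshot) -> float:
    """Dipole magnitude in Debye about the mass-weighted centre."""
    q = snapshot.topology.charges
    m = snapshot.topology.masses
    com = (m[:, None] * snapshot.coords).sum(axis=0) / m.sum()
    mu = (q[:, None] * (snapshot.coords - com)).sum(axis=0)
    return float(np.linalg.norm(mu)) * DEBYE_PER_E_ANGSTROM


def _gyration_tensor(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    com = (masses[:, None] * coords).sum(axis=0) / masses.sum()
    d = coords - com
    return (masses[:, None, None] * d[:, :, None] * d[:, None, :]).sum(
        axis=0
    ) / masses.sum()


def inertia_and_gyration(snapshot: MoleculeSnapshot) -> dict[str, float]:
    m = snapshot.topology.masses
    coords = snapshot.coords
    com = (m[:, None] * coords).sum(axis=0) / m.sum()
    d = coords - com
    r2 = (d**2).sum(axis=1)
    inertia = np.diag((m * r2).sum() * np.ones(3)) - (
        m[:, None, None] * d[:, :, None] * d[:, None, :]
    ).sum(axis=0)
    i1, i2, i3 = np.sort(np.linalg.eigvalsh(inertia))
    shape_factor = i2 / (i1 * i3) if i1 * i3 > 0 else 0.0

    lam = np.sort(np.linalg.eigvalsh(_gyration_tensor(coords, m)))
    lam = np.clip(lam, 0.0, None)
    rg2 = lam.sum()
    asph = lam[2] - (lam[0] + lam[1]) / 2
    acyl = lam[1] - lam[0]
    kappa2 = (asph**2 + 0.75 * acyl**2) / rg2**2 if rg2 > 0 else 0.0
    return {
        "I1": float(i1),
        "I2": float(i2),
        "I3": float(i3),
        "I1/I2": float(i1 / i2) if i2 > 0 else 0.0,
        "I1/I3": float(i1 / i3) if i3 > 0 else 0.0,
        "I2/I3": float(i2 / i3) if i3 > 0 else 0.0,
        "inertialShapeFactor": float(shape_factor),
        "Rg": float(np.sqrt(rg2)),
        "asphericity": float(asph),
        "acylindricity": float(acyl),
        "kappa2": float(kappa2),
    }


def gravitation(snapshot: MoleculeSnapshot) -> tuple[float, float]:
    """Gravitation indices: sum of m_i m_j / r_ij^2 over all pairs (grav1)
    and over bonded pairs only (grav2)."""
    m = snapshot.topology.masses
    dist = snapshot.distances
    n = len(m)
    if n < 2:
        return 0.0, 0.0
    iu = np.triu_indices(n, 1)
    r = dist[iu]
    mm = m[iu[0]] * m[iu[1]]
    grav1 = float((mm[r > 0] / r[r > 0] ** 2).sum())
    bonds = snapshot.topology.bonds
    if len(bonds):
        rb = dist[bonds[:, 0], bonds[:, 1]]
        mb = m[bonds[:, 0]] * m[bonds[:, 1]]
        grav2 = float((mb[rb > 0] / rb[rb > 0] ** 2).sum())
    else:
        grav2 = 0.0
    return grav1, grav2


def molvolume(snapshot: MoleculeSnapshot, grid: float = VOLUME_GRID) -> float:
    """Volume of the union of vdW spheres by cubic-grid voxel counting."""
    radii = snapshot.topology.vdw_radii()
    coords = snapshot.coords
    pad = radii.max() + grid
    lo = coords.min(axis=0) - pad
    hi = coords.max(axis=0) + pad
    axes = [np.arange(lo[k] + grid / 2, hi[k], grid) for k in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    inside = np.zeros(len(pts), dtype=bool)
    for c, r in zip(coords, radii):
        sub = ~inside
        inside[sub] = ((pts[sub] - c) ** 2).sum(axis=1) <= r**2
    return float(inside.sum()) * grid**3


def _principal_frame(snapshot: MoleculeSnapshot) -> np.ndarray:
    """Coordinates rotated into the gyration-tensor principal axes."""
    m = snapshot.topology.masses
    tensor = _gyration_tensor(snapshot.coords, m)
    _, vecs = np.linalg.eigh(tensor)
    com = (m[:, None] * snapshot.coords).sum(axis=0) / m.sum()
    return (snapshot.coords - com) @ vecs


def shadow_indices(
    snapshot: MoleculeSnapshot, grid: float = SHADOW_GRID
) -> dict[str, float]:
    """Projected areas of the union of atom disks onto the three principal
    planes (S1..S3) and the same normalised by the enclosing rectangle
    (S4..S6)."""
    radii = snapshot.topology.vdw_radii()
    coords = _principal_frame(snapshot)
    out: dict[str, float] = {}
    for idx, (a, b) in enumerate(((1, 2), (0, 2), (0, 1))):
        pts2 = coords[:, [a, b]]
        pad = radii.max() + grid
        lo = pts2.min(axis=0) - pad
        hi = pts2.max(axis=0) + pad
        ga = np.arange(lo[0] + grid / 2, hi[0], grid)
        gb = np.arange(lo[1] + grid / 2, hi[1], grid)
        gx, gy = np.meshgrid(ga, gb, indexing="ij")
        cells = np.column_stack([gx.ravel(), gy.ravel()])
        inside = np.zeros(len(cells), dtype=bool)
        for c, r in zip(pts2, radii):
            sub = ~inside
            inside[sub] = ((cells[sub] - c) ** 2).sum(axis=1) <= r**2
        area = float(inside.sum()) * grid**2
        # enclosing rectangle of the projected disks (tight per-atom extents)
        ext_lo = (pts2 - radii[:, None]).min(axis=0)
        ext_hi = (pts2 + radii[:, None]).max(axis=0)
        rect = float((ext_hi[0] - ext_lo[0]) * (ext_hi[1] - ext_lo[1]))
        out[f"S{idx + 1}"] = area
        out[f"S{idx + 4}"] = area / rect if rect > 0 else 0.0
    return out


def pbf(snapshot: MoleculeSnapshot) -> float:
    """Plane-of-best-fit score: mean |distance| to the least-squares plane."""
    if snapshot.n_atoms < 3:
        return 0.0
    centered = snapshot.centered
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[-1]
    return float(np.abs(centered @ normal).mean())


def _backbone_path(topology) -> list[int]:
    """One shortest path realising the graph diameter; ties broken by the
    lexicographically smallest atom-id sequence."""
    topo = topology.topo_dist
    n = len(topo)
    if n == 1:
        return [0]
    diameter = topo.max()
    best: list[int] | None = None
    ends = np.argwhere(topo == diameter)
    for s, t in ends:
        if s > t:
            continue
        path = _lex_shortest_path(topology.graph, int(s), int(t), topology.atom_ids)
        key = [int(topology.atom_ids[k]) for k in path]
        if best is None or key < [int(topology.atom_ids[k]) for k in best]:
            best = path
    return best if best is not None else [0]


def _lex_shortest_path(graph: nx.Graph, s: int, t: int, atom_ids) -> list[int]:
    # among shortest paths s->t pick the one whose atom-id sequence is smallest
    target_len = nx.shortest_path_length(graph, s, t)
    best = None
    for path in nx.all_shortest_paths(graph, s, t):
        key = [int(atom_ids[k]) for k in path]
        if best is None or key < best[0]:
            best = (key, path)
    assert best is not None and len(best[1]) == target_len + 1
    return best[1]


def chain_measures(snapshot: MoleculeSnapshot) -> dict[str, float]:
    coords = snapshot.coords
    m = snapshot.topology.masses
    com = (m[:, None] * coords).sum(axis=0) / m.sum()
    span = float(np.linalg.norm(coords - com, axis=1).max())
    diameter_geo = float(snapshot.distances.max())

    path = _backbone_path(snapshot.topology)
    out = {
        "span": span,
        "diameter3D_geo": diameter_geo,
        "Ree": 0.0,
        "Lcontour": 0.0,
        "lk": 0.0,
    }
    for k in range(1, 11):
        out[f"phi{k}"] = 0.0
    if len(path) < 2:
        return out

    seg = np.array(
        [snapshot.distances[path[i], path[i + 1]] for i in range(len(path) - 1)]
    )
    ree = float(snapshot.distances[path[0], path[-1]])
    lcontour = float(seg.sum())
    out["Ree"] = ree
    out["Lcontour"] = lcontour
    out["lk"] = ree**2 / lcontour if lcontour > 0 else 0.0

    m_steps = len(path) - 1
    for k in range(1, 11):
        if m_steps < k:
            continue
        ratios = []
        for i in range(m_steps - k + 1):
            direct = snapshot.distances[path[i], path[i + k]]
            along = seg[i : i + k].sum()
            ratios.append(direct / along if along > 0 else 0.0)
        out[f"phi{k}"] = float(np.mean(ratios))
    return out


def geometric(snapshot: MoleculeSnapshot) -> dict[str, float]:
    """All 41 set-2 descriptors for one molecule-frame."""
    out: dict[str, float] = {"dipole_debye": dipole(snapshot)}
    out.update(inertia_and_gyration(snapshot))
    g1, g2 = gravitation(snapshot)
    out["grav1"], out["grav2"] = g1, g2
    out["molvolume"] = molvolume(snapshot)
    out.update(shadow_indices(snapshot))
    out["PBF"] = pbf(snapshot)
    out.update(chain_measures(snapshot))
    return {name: out[name] for name in NAMES}
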