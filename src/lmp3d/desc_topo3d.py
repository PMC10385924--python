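"""Set 1 — 3D topology and 3D connectivity descriptors.

Classic topological indices (Wiener, Harary, Balaban J, eccentricity
family, Randic-type chi) evaluated on the *geometric* distance matrix of a
conformer rather than on bond counts, plus the same family on the
hydrogen-suppressed graph (suffix ``_hs``).
"""

from __future__ import annotations

import numpy as np

from .molecular_model import MoleculeSnapshot, MoleculeTopology, make_snapshot

_BASE_NAMES = (
    "W3D",
    "H3D",
    "AGD",
    "J3D",
    "radius3D",
    "diameter3D",
    "meanEcc3D",
    "petitjean3D",
    "chi0_3D",
    "chi1_3D",
    "chi2_3D",
)

NAMES = _BASE_NAMES + tuple(f"{n}_hs" for n in _BASE_NAMES)


def _two_paths(adjacency: np.ndarray) -> list[tuple[int, int, int]]:
    """Ordered-once 2-paths i-j-k (i < k) of the bond graph."""
    n = len(adjacency)
    paths = []
    for j in range(n):
        nbrs = np.flatnonzero(adjacency[j])
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                paths.append((int(nbrs[a]), j, int(nbrs[b])))
    return paths


def _indices(dist: np.ndarray, topo: MoleculeTopology) -> dict[str, float]:
    n = len(dist)
    if n < 2:
        return {name: 0.0 for name in _BASE_NAMES}
    iu = np.triu_indices(n, 1)
    upper = dist[iu]
    w3d = float(upper.sum())
    h3d = float((1.0 / upper[upper > 0]).sum())
    agd = w3d / (n * (n - 1) / 2)
    ecc = dist.max(axis=1)
    radius = float(ecc.min())
    diameter = float(ecc.max())
    petitjean = (diameter - radius) / radius if radius > 0 else 0.0

    bonds = topo.bonds
    n_bonds = len(bonds)
    row_sums = dist.sum(axis=1)
    if n_bonds:
        cyclomatic = n_bonds - n + 1
        s_i = row_sums[bonds[:, 0]]
        s_j = row_sums[bonds[:, 1]]
        j3d = (
            n_bonds
            / (cyclomatic + 1)
            * float(((s_i * s_j) ** -0.5).sum())
        )
        bond_lengths = dist[bonds[:, 0], bonds[:, 1]]
        mean_bond = float(bond_lengths.mean())
    else:
        j3d = 0.0
        mean_bond = 0.0

    degree = topo.adjacency.sum(axis=1).astype(float)
    nz = degree > 0
    chi0 = float((degree[nz] ** -0.5).sum()) * mean_bond
    chi1 = (
        float(((degree[bonds[:, 0]] * degree[bonds[:, 1]]) ** -0.5).sum())
        * mean_bond
        if n_bonds
        else 0.0
    )
    chi2 = (
        sum(
            (degree[i] * degree[j] * degree[k]) ** -0.5
            for i, j, k in _two_paths(topo.adjacency)
        )
        * mean_bond
    )

    return {
        "W3D": w3d,
        "H3D": h3d,
        "AGD": agd,
        "J3D": j3d,
        "radius3D": radius,
        "diameter3D": diameter,
        "meanEcc3D": float(ecc.mean()),
        "petitjean3D": petitjean,
        "chi0_3D": chi0,
        "chi1_3D": chi1,
        "chi2_3D": float(chi2),
    }


def topo3d(snapshot: MoleculeSnapshot) -> dict[str, float]:
    """All 22 set-1 descriptors (plain + hydrogen-suppressed) for one frame."""
    block = _indices(snapshot.distances, snapshot.topology)

    hs = snapshot.topology.hydrogen_suppressed()
    if hs is None:
        hs_block = {name: 0.0 for name in _BASE_NAMES}
    elif hs is snapshot.topology:
        hs_block = dict(block)
    else:
        keep = np.isin(snapshot.topology.atom_ids, hs.atom_ids)
        hs_snap = make_snapshot(hs, snapshot.timestep, snapshot.coords[keep])
        hs_block = _indices(hs_snap.distances, hs)
    out = dict(block)
    for name in _BASE_NAMES:
        out[f"{name}_hs"] = hs_block[name]
    return out
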