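"""Per-molecule structure: bond graphs, topological distances, element and
property assignment, and unwrapped per-frame geometry.

The static system definition (masses, charges, bonds, molecule membership)
comes from the data file; per-frame coordinates come from the dump.  Wrapped
coordinates are converted to unwrapped ones by a breadth-first walk over the
bond graph using the minimum-image convention, which is exact whenever every
bond is shorter than half the shortest box side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import (
    BondLongerThanHalfBox,
    DisconnectedMolecule,
    NonOrthogonalBox,
)
from .lammps_io import DataFileContent, DumpFrame
from .properties import (
    PROPERTY_NAMES,
    PROPERTY_TABLE,
    carbon_scaled,
    infer_element,
)

#: Weight-scheme codes used across descriptor families.
#: u = unit, m = mass, c = charge, v = vdW volume, e = electronegativity,
#: p = polarizability, i = ionization potential, a = electron affinity.
SCHEME_PROPERTY = {
    "m": "mass",
    "v": "vdw_volume",
    "e": "electronegativity",
    "p": "polarizability",
    "i": "ionization_potential",
    "a": "electron_affinity",
}


@dataclass
class MoleculeTopology:
    """Static structure of one molecule, atoms in ascending atom-id order."""

    mol_id: int
    atom_ids: np.ndarray  # (N,) global LAMMPS atom ids, sorted
    elements: list[str]
    masses: np.ndarray  # (N,) g/mol
    charges: np.ndarray  # (N,) e
    bonds: np.ndarray  # (B, 2) local 0-based indices, i < j
    adjacency: np.ndarray  # (N, N) bool
    topo_dist: np.ndarray  # (N, N) int bond counts
    graph: nx.Graph = field(repr=False, default=None)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_ids)

    def weights(self, scheme: str) -> np.ndarray:
        """Atomic weight vector for a one-letter scheme code.

        Charge ("c") is the raw partial charge in e; every other property is
        scaled relative to carbon so that a carbon atom weighs 1.
        """
        if scheme == "u":
            return np.ones(self.n_atoms)
        if scheme == "c":
            return self.charges.copy()
        prop = SCHEME_PROPERTY[scheme]
        return np.array([carbon_scaled(prop, el) for el in self.elements])

    def vdw_radii(self) -> np.ndarray:
        return np.array([PROPERTY_TABLE[el].vdw_radius for el in self.elements])

    def hydrogen_suppressed(self) -> "MoleculeTopology | None":
        """Copy of this molecule with H atoms and their bonds removed.

        Returns None when fewer than one heavy atom remains connected; a
        molecule with no hydrogens returns itself.
        """
        heavy = [k for k, el in enumerate(self.elements) if el != "H"]
        if len(heavy) == self.n_atoms:
            return self
        if not heavy:
            return None
        remap = {old: new for new, old in enumerate(heavy)}
        bonds = np.array(
            [
                (remap[i], remap[j])
                for i, j in self.bonds
                if i in remap and j in remap
            ],
            dtype=int,
        ).reshape(-1, 2)
        sub = _build_molecule(
            self.mol_id,
            self.atom_ids[heavy],
            [self.elements[k] for k in heavy],
            self.masses[heavy],
            self.charges[heavy],
            bonds,
            require_connected=False,
        )
        return sub


@dataclass
class SystemTopology:
    """All molecules of the system plus flat per-atom lookups."""

    molecules: dict[int, MoleculeTopology]
    atom_index: dict[int, tuple[int, int]]  # atom id -> (mol id, local index)

    @property
    def molecule_ids(self) -> list[int]:
        return sorted(self.molecules)

    @property
    def total_mass(self) -> float:
        return float(sum(m.masses.sum() for m in self.molecules.values()))


@dataclass
class MoleculeSnapshot:
    """One molecule at one frame: unwrapped geometry plus cached matrices."""

    topology: MoleculeTopology
    timestep: int
    coords: np.ndarray  # (N, 3) unwrapped, A
    centered: np.ndarray  # coords minus the unweighted centroid
    distances: np.ndarray  # (N, N) Euclidean distance matrix

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms


def _build_molecule(
    mol_id, atom_ids, elements, masses, charges, bonds, require_connected=True
) -> MoleculeTopology:
    n = len(atom_ids)
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    graph.add_edges_from(map(tuple, bonds))
    if require_connected and n > 0 and not nx.is_connected(graph):
        sizes = [len(c) for c in nx.connected_components(graph)]
        raise DisconnectedMolecule(mol_id, sizes)
    adjacency = np.zeros((n, n), dtype=bool)
    for i, j in bonds:
        adjacency[i, j] = adjacency[j, i] = True
    topo = np.full((n, n), -1, dtype=int)
    for src, lengths in nx.all_pairs_shortest_path_length(graph):
        for dst, d in lengths.items():
            topo[src, dst] = d
    np.fill_diagonal(topo, 0)
    return MoleculeTopology(
        mol_id=mol_id,
        atom_ids=np.asarray(atom_ids, dtype=int),
        elements=list(elements),
        masses=np.asarray(masses, dtype=float),
        charges=np.asarray(charges, dtype=float),
        bonds=np.asarray(bonds, dtype=int).reshape(-1, 2),
        adjacency=adjacency,
        topo_dist=topo,
        graph=graph,
    )


def build_topology(data: DataFileContent) -> SystemTopology:
    """Partition atoms by molecule id and build per-molecule structure.

    Raises :class:`DisconnectedMolecule` when a molecule's bond graph is not
    connected (including the case of a bond joining two molecule ids, which
    leaves at least one of them split).
    """
    by_mol: dict[int, list] = {}
    for atom in data.atoms:
        by_mol.setdefault(atom.mol, []).append(atom)

    atom_mol = {a.id: a.mol for a in data.atoms}
    for _, _, i, j in data.bonds:
        if atom_mol[i] != atom_mol[j]:
            raise DisconnectedMolecule(
                atom_mol[i], [len(by_mol[atom_mol[i]]), len(by_mol[atom_mol[j]])]
            )

    molecules: dict[int, MoleculeTopology] = {}
    atom_index: dict[int, tuple[int, int]] = {}
    for mol_id, atoms in sorted(by_mol.items()):
        atoms = sorted(atoms, key=lambda a: a.id)
        local = {a.id: k for k, a in enumerate(atoms)}
        bonds = np.array(
            sorted(
                tuple(sorted((local[i], local[j])))
                for _, _, i, j in data.bonds
                if i in local
            ),
            dtype=int,
        ).reshape(-1, 2)
        molecules[mol_id] = _build_molecule(
            mol_id,
            [a.id for a in atoms],
            [infer_element(data.masses[a.type]) for a in atoms],
            [data.masses[a.type] for a in atoms],
            [a.charge for a in atoms],
            bonds,
        )
        for aid, k in local.items():
            atom_index[aid] = (mol_id, k)
    return SystemTopology(molecules=molecules, atom_index=atom_index)


def unwrap_frame(
    frame: DumpFrame, topo: SystemTopology
) -> dict[int, np.ndarray]:
    """Unwrapped coordinates per molecule id, rows in ascending atom-id order.

    Unwrapped dumps pass through unchanged.  Wrapped dumps are unwrapped per
    molecule by a breadth-first traversal from the lowest atom id, placing
    each newly reached atom at the minimum-image position relative to its
    already-placed bonded neighbour.
    """
    if frame.triclinic and frame.coord_kind == "wrapped":
        raise NonOrthogonalBox(
            "wrapped coordinates in a triclinic box cannot be unwrapped"
        )
    id_to_row = {int(aid): k for k, aid in enumerate(frame.ids)}
    box_lengths = np.array([hi - lo for lo, hi in frame.box])
    half_min = box_lengths[box_lengths > 0].min() / 2 if box_lengths.any() else 0.0

    out: dict[int, np.ndarray] = {}
    for mol_id, mol in topo.molecules.items():
        rows = [id_to_row[int(aid)] for aid in mol.atom_ids]
        coords = frame.coords[rows].astype(float)
        if frame.coord_kind == "unwrapped":
            out[mol_id] = coords
            continue
        # Integer image counts keep the arithmetic exact: each unwrapped
        # coordinate is one wrapped coordinate plus a whole number of box
        # lengths, so wrapped and unwrapped inputs reproduce identical
        # geometries bit for bit whenever the values are representable.
        images = np.zeros((mol.n_atoms, 3), dtype=int)
        for i, j in nx.bfs_edges(mol.graph, source=0):
            raw = (coords[j] + box_lengths * images[i]) - (
                coords[i] + box_lengths * images[i]
            )
            shift = np.round(raw / box_lengths).astype(int)
            images[j] = images[i] - shift
            delta = (coords[j] + box_lengths * images[j]) - (
                coords[i] + box_lengths * images[i]
            )
            length = float(np.linalg.norm(delta))
            if length > half_min:
                raise BondLongerThanHalfBox(
                    int(mol.atom_ids[i]), int(mol.atom_ids[j]), length, half_min
                )
        out[mol_id] = coords + box_lengths * images
    return out


def geometry_matrices(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Euclidean distance matrix and centroid-centered coordinates."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    centered = coords - coords.mean(axis=0)
    dist = squareform(pdist(coords)) if len(coords) > 1 else np.zeros((1, 1))
    return dist, centered


def make_snapshot(
    mol: MoleculeTopology, timestep: int, coords: np.ndarray
) -> MoleculeSnapshot:
    """Snapshot with cached distance matrix and centered coordinates.

    Coordinates are re-anchored so the first atom sits at the origin: every
    descriptor is translation-invariant, and anchoring makes the computed
    values bitwise independent of whole-molecule lattice translations (the
    only difference between wrapped and unwrapped input).
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    coords = coords - coords[0]
    dist, centered = geometry_matrices(coords)
    return MoleculeSnapshot(
        topology=mol,
        timestep=timestep,
        coords=coords,
        centered=centered,
        distances=dist,
    )
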