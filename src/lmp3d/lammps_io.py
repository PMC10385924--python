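"""Readers for LAMMPS data files (atom style "full") and text dump trajectories.

Section order in the data file and column order in the dump header are both
arbitrary; everything is resolved from the headers themselves.  Only
orthogonal boxes are supported and scaled dump coordinates (xs/ys/zs) are
rejected rather than silently converted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    CountMismatch,
    MalformedRecord,
    MissingColumn,
    MissingSection,
    MixedCoordinateKinds,
    ScaledCoordinatesUnsupported,
    TruncatedFrame,
    AtomSetMismatch,
)

# Section names a typical data file contains.  Coeff sections are recognised
# so their bodies can be skipped cleanly.
_BODY_SECTIONS = {
    "Masses",
    "Atoms",
    "Velocities",
    "Bonds",
    "Angles",
    "Dihedrals",
    "Impropers",
    "Pair Coeffs",
    "PairIJ Coeffs",
    "Bond Coeffs",
    "Angle Coeffs",
    "Dihedral Coeffs",
    "Improper Coeffs",
}

_HEADER_COUNT_RE = re.compile(
    r"^\s*(\d+)\s+(atoms|bonds|angles|dihedrals|impropers|atom types|"
    r"bond types|angle types|dihedral types|improper types)\s*$"
)
_BOX_RE = re.compile(
    r"^\s*([-\d.eE+]+)\s+([-\d.eE+]+)\s+(xlo xhi|ylo yhi|zlo zhi)\s*$"
)


@dataclass
class Atom:
    """One Atoms row in atom style "full" (charge in e, coordinates in A)."""

    id: int
    mol: int
    type: int
    charge: float
    x: float
    y: float
    z: float
    image: tuple[int, int, int] | None = None


@dataclass
class DataFileContent:
    """Parsed static system definition."""

    masses: dict[int, float]
    atoms: list[Atom]
    bonds: list[tuple[int, int, int, int]]  # (bond-id, bond-type, i, j)
    angles: list[tuple[int, ...]] = field(default_factory=list)
    dihedrals: list[tuple[int, ...]] = field(default_factory=list)
    box: tuple[tuple[float, float], ...] = ()

    @property
    def atom_ids(self) -> set[int]:
        return {a.id for a in self.atoms}


@dataclass
class DumpFrame:
    """One snapshot of a text dump: box bounds, column names, sorted records."""

    timestep: int
    box: tuple[tuple[float, float], ...]
    periodic: tuple[bool, bool, bool]
    columns: list[str]
    ids: np.ndarray  # (N,) int, sorted ascending
    mols: np.ndarray  # (N,) int
    types: np.ndarray  # (N,) int
    coords: np.ndarray  # (N, 3) float
    coord_kind: str  # "wrapped" | "unwrapped"
    triclinic: bool = False


def _strip_comment(line: str) -> str:
    return line.split("#", 1)[0].rstrip("\r\n")


def _section_name(line: str) -> str | None:
    bare = _strip_comment(line).strip()
    return bare if bare in _BODY_SECTIONS else None


def parse_data(path) -> DataFileContent:
    """Parse a LAMMPS data file, atom style "full".

    Sections may appear in any order; "#" comments are ignored; image flags
    on Atoms lines are retained when present.  Raises :class:`MissingSection`
    if Masses, Atoms or Bonds (with a non-zero bond count) is absent,
    :class:`CountMismatch` if a section's row count disagrees with the header,
    and :class:`MalformedRecord` for rows with the wrong field count.
    """
    with open(path, "r", newline="") as fh:
        lines = fh.read().splitlines()

    counts: dict[str, int] = {}
    box = {}
    # Header: everything before the first recognised section keyword.
    i = 1  # first line is a free-form comment
    n = len(lines)
    while i < n and _section_name(lines[i]) is None:
        bare = _strip_comment(lines[i])
        m = _HEADER_COUNT_RE.match(bare)
        if m:
            counts[m.group(2)] = int(m.group(1))
        m = _BOX_RE.match(bare)
        if m:
            box[m.group(3)[:1]] = (float(m.group(1)), float(m.group(2)))
        i += 1

    sections: dict[str, list[tuple[int, str]]] = {}
    while i < n:
        name = _section_name(lines[i])
        if name is None:
            i += 1
            continue
        i += 1
        # skip blank line(s) after the keyword
        while i < n and not _strip_comment(lines[i]).strip():
            i += 1
        body: list[tuple[int, str]] = []
        while i < n:
            bare = _strip_comment(lines[i]).strip()
            if not bare:
                break
            body.append((i + 1, bare))
            i += 1
        sections[name] = body

    for required in ("Masses", "Atoms"):
        if required not in sections:
            raise MissingSection(required)
    if "Bonds" not in sections and counts.get("bonds", 1) != 0:
        raise MissingSection("Bonds")

    masses: dict[int, float] = {}
    for line_no, row in sections["Masses"]:
        parts = row.split()
        if len(parts) != 2:
            raise MalformedRecord(line_no, "2 fields (type mass)", row)
        masses[int(parts[0])] = float(parts[1])

    atoms: list[Atom] = []
    for line_no, row in sections["Atoms"]:
        parts = row.split()
        if len(parts) not in (7, 10):
            raise MalformedRecord(
                line_no, "7 or 10 fields (id mol type q x y z [ix iy iz])", row
            )
        image = tuple(int(v) for v in parts[7:10]) if len(parts) == 10 else None
        atoms.append(
            Atom(
                id=int(parts[0]),
                mol=int(parts[1]),
                type=int(parts[2]),
                charge=float(parts[3]),
                x=float(parts[4]),
                y=float(parts[5]),
                z=float(parts[6]),
                image=image,
            )
        )

    bonds: list[tuple[int, int, int, int]] = []
    for line_no, row in sections.get("Bonds", []):
        parts = row.split()
        if len(parts) != 4:
            raise MalformedRecord(line_no, "4 fields (id type i j)", row)
        bonds.append(tuple(int(v) for v in parts))  # type: ignore[arg-type]

    angles = [
        tuple(int(v) for v in row.split()) for _, row in sections.get("Angles", [])
    ]
    dihedrals = [
        tuple(int(v) for v in row.split()) for _, row in sections.get("Dihedrals", [])
    ]

    for key, section, found in (
        ("atoms", "Atoms", len(atoms)),
        ("bonds", "Bonds", len(bonds)),
        ("atom types", "Masses", len(masses)),
    ):
        if key in counts and counts[key] != found:
            raise CountMismatch(section, counts[key], found)

    box_tuple = tuple(box.get(ax, (0.0, 0.0)) for ax in "xyz")
    content = DataFileContent(
        masses=masses,
        atoms=atoms,
        bonds=bonds,
        angles=angles,
        dihedrals=dihedrals,
        box=box_tuple,
    )
    _validate_data(content)
    return content


def _validate_data(content: DataFileContent) -> None:
    ids = [a.id for a in content.atoms]
    if len(ids) != len(set(ids)):
        raise MalformedRecord(0, "unique atom ids", "duplicate atom id")
    id_set = set(ids)
    for bond in content.bonds:
        _, _, i, j = bond
        if i not in id_set or j not in id_set:
            raise MalformedRecord(0, "bond endpoints among atom ids", str(bond))
    for atom in content.atoms:
        if atom.type not in content.masses:
            raise MalformedRecord(
                0, "atom type present in Masses", f"type {atom.type}"
            )


_COORD_WRAPPED = ("x", "y", "z")
_COORD_UNWRAPPED = ("xu", "yu", "zu")
_COORD_SCALED = ("xs", "ys", "zs", "xsu", "ysu", "zsu")


def parse_dump(path) -> list[DumpFrame]:
    """Parse a LAMMPS text dump into a list of frames sorted by atom id.

    Column positions are resolved from each frame's ``ITEM: ATOMS`` header.
    Coordinates must be either wrapped (x y z) or unwrapped (xu yu zu);
    scaled coordinates are rejected.
    """
    with open(path, "r", newline="") as fh:
        lines = fh.read().splitlines()

    frames: list[DumpFrame] = []
    i, n = 0, len(lines)
    while i < n:
        line = lines[i].strip()
        if not line.startswith("ITEM: TIMESTEP"):
            i += 1
            continue
        try:
            timestep = int(lines[i + 1].strip())
            assert lines[i + 2].strip().startswith("ITEM: NUMBER OF ATOMS")
            n_atoms = int(lines[i + 3].strip())
            box_header = lines[i + 4].strip()
            assert box_header.startswith("ITEM: BOX BOUNDS")
            bounds = []
            for k in range(3):
                parts = lines[i + 5 + k].split()
                bounds.append((float(parts[0]), float(parts[1])))
            atoms_header = lines[i + 8].strip()
            assert atoms_header.startswith("ITEM: ATOMS")
        except (IndexError, AssertionError, ValueError) as exc:
            raise TruncatedFrame(f"malformed frame near line {i + 1}") from exc

        flags = box_header.removeprefix("ITEM: BOX BOUNDS").split()
        triclinic = any(f in ("xy", "xz", "yz") for f in flags)
        periodic = tuple("pp" == f for f in flags[-3:]) if len(flags) >= 3 else (
            True,
            True,
            True,
        )
        columns = atoms_header.removeprefix("ITEM: ATOMS").split()
        col = {name: k for k, name in enumerate(columns)}

        for required in ("id", "mol", "type"):
            if required not in col:
                raise MissingColumn(required)
        has_wrapped = all(c in col for c in _COORD_WRAPPED)
        has_unwrapped = all(c in col for c in _COORD_UNWRAPPED)
        if has_wrapped and has_unwrapped:
            raise MixedCoordinateKinds(
                "dump contains both x/y/z and xu/yu/zu columns"
            )
        if not has_wrapped and not has_unwrapped:
            if any(c in col for c in _COORD_SCALED):
                raise ScaledCoordinatesUnsupported(
                    "scaled coordinates (xs/ys/zs) are not supported"
                )
            raise MissingColumn("x/y/z or xu/yu/zu")
        coord_names = _COORD_UNWRAPPED if has_unwrapped else _COORD_WRAPPED
        coord_kind = "unwrapped" if has_unwrapped else "wrapped"

        body = lines[i + 9 : i + 9 + n_atoms]
        if len(body) < n_atoms:
            raise TruncatedFrame(
                f"frame at timestep {timestep}: expected {n_atoms} atom rows, "
                f"found {len(body)}"
            )
        try:
            table = np.array([row.split() for row in body], dtype=float)
        except ValueError as exc:
            raise TruncatedFrame(
                f"frame at timestep {timestep}: non-numeric or ragged atom rows"
            ) from exc
        if table.shape[1] != len(columns):
            raise TruncatedFrame(
                f"frame at timestep {timestep}: row width {table.shape[1]} != "
                f"{len(columns)} declared columns"
            )

        ids = table[:, col["id"]].astype(int)
        if len(set(ids.tolist())) != len(ids):
            raise TruncatedFrame(
                f"frame at timestep {timestep}: duplicate atom ids"
            )
        order = np.argsort(ids, kind="stable")
        frames.append(
            DumpFrame(
                timestep=timestep,
                box=tuple(bounds),
                periodic=periodic,  # type: ignore[arg-type]
                columns=columns,
                ids=ids[order],
                mols=table[order, col["mol"]].astype(int),
                types=table[order, col["type"]].astype(int),
                coords=table[np.ix_(order, [col[c] for c in coord_names])],
                coord_kind=coord_kind,
                triclinic=triclinic,
            )
        )
        i += 9 + n_atoms
    return frames


@dataclass
class ConsistencyReport:
    n_atoms: int
    n_molecules: int
    molecule_ids: list[int]
    atoms_per_molecule: dict[int, int]


def check_consistency(
    data: DataFileContent, frames: list[DumpFrame]
) -> ConsistencyReport:
    """Verify that every frame carries exactly the data file's atom ids."""
    data_ids = data.atom_ids
    for frame in frames:
        frame_ids = set(frame.ids.tolist())
        if frame_ids != data_ids:
            raise AtomSetMismatch(data_ids - frame_ids, frame_ids - data_ids)
    per_mol: dict[int, int] = {}
    for atom in data.atoms:
        per_mol[atom.mol] = per_mol.get(atom.mol, 0) + 1
    return ConsistencyReport(
        n_atoms=len(data.atoms),
        n_molecules=len(per_mol),
        molecule_ids=sorted(per_mol),
        atoms_per_molecule=per_mol,
    )
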