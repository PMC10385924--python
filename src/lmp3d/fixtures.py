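"""Synthetic LAMMPS data/dump fixture generator with exact ground truth.

Small rigid molecules (methane, planar rings), ideal zig-zag alkanes and
seeded random-walk chains are written as atom-style "full" data files and
text dump trajectories, optionally wrapped into the periodic box, while the
exact unwrapped coordinates, bonds, masses and charges are retained as
ground truth.  Everything is seeded, so two generations with the same spec
are byte-identical and no external download is ever needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import SpecInvalid

_TYPE_MASSES = {"C": 12.011, "H": 1.008, "O": 15.999, "CH2": 14.027}


@dataclass
class MoleculeTemplate:
    elements: list[str]
    coords: np.ndarray  # (N, 3)
    bonds: list[tuple[int, int]]  # local 0-based


def methane() -> MoleculeTemplate:
    """CH4: tetrahedral, C-H = 1.09 A."""
    d = 1.09 / math.sqrt(3.0)
    coords = np.array(
        [
            [0.0, 0.0, 0.0],
            [d, d, d],
            [d, -d, -d],
            [-d, d, -d],
            [-d, -d, d],
        ]
    )
    return MoleculeTemplate(
        elements=["C", "H", "H", "H", "H"],
        coords=coords,
        bonds=[(0, 1), (0, 2), (0, 3), (0, 4)],
    )


def ideal_alkane(n: int, bond: float = 1.54) -> MoleculeTemplate:
    """n-carbon zig-zag backbone with tetrahedral bond angles."""
    if n < 2:
        raise SpecInvalid("alkane needs >= 2 carbons")
    half_angle = math.radians(109.47 / 2.0)
    dx = bond * math.sin(half_angle)
    dz = bond * math.cos(half_angle)
    coords = np.array(
        [[i * dx, 0.0, (i % 2) * dz] for i in range(n)]
    )
    return MoleculeTemplate(
        elements=["C"] * n,
        coords=coords,
        bonds=[(i, i + 1) for i in range(n - 1)],
    )


def random_walk_chain(
    n: int, bond: float, seed: int
) -> MoleculeTemplate:
    """Freely jointed chain: fixed bond length, uniform random directions."""
    if n < 2:
        raise SpecInvalid("chain needs >= 2 atoms")
    rng = np.random.default_rng(seed)
    coords = np.zeros((n, 3))
    for i in range(1, n):
        v = rng.normal(size=3)
        coords[i] = coords[i - 1] + bond * v / np.linalg.norm(v)
    return MoleculeTemplate(
        elements=["C"] * n,
        coords=coords,
        bonds=[(i, i + 1) for i in range(n - 1)],
    )


def planar_ring(n: int, bond: float = 1.4) -> MoleculeTemplate:
    """n-membered carbon ring in the z = 0 plane."""
    if n < 3:
        raise SpecInvalid("ring needs >= 3 atoms")
    radius = bond / (2.0 * math.sin(math.pi / n))
    coords = np.array(
        [
            [radius * math.cos(2 * math.pi * k / n),
             radius * math.sin(2 * math.pi * k / n),
             0.0]
            for k in range(n)
        ]
    )
    return MoleculeTemplate(
        elements=["C"] * n,
        coords=coords,
        bonds=[(k, (k + 1) % n) for k in range(n)],
    )


@dataclass
class FixtureSpec:
    """Declarative description of a synthetic system."""

    template: MoleculeTemplate
    copies: int = 1
    box: tuple[float, float, float] = (30.0, 30.0, 30.0)
    frames: int = 1
    seed: int = 0
    wrap: bool = False
    charge_pattern: str | list[float] = "neutral-zero"  # or "alternating"
    charge_magnitude: float = 0.3
    rigid_motion: bool = True  # seeded rotation+translation per frame


@dataclass
class GroundTruth:
    """Exact in-memory truth mirroring the written files."""

    elements: list[str]  # per atom, ascending atom id
    masses: list[float]
    charges: list[float]
    mols: list[int]
    bonds: list[tuple[int, int, int, int]]
    box: tuple[tuple[float, float], ...]
    frames: list[dict[int, np.ndarray]] = field(default_factory=list)
    timesteps: list[int] = field(default_factory=list)


def _charges_for(spec: FixtureSpec, n: int) -> list[float]:
    if isinstance(spec.charge_pattern, list):
        if len(spec.charge_pattern) != n:
            raise SpecInvalid("per-atom charge list length mismatch")
        return list(spec.charge_pattern)
    if spec.charge_pattern == "neutral-zero":
        return [0.0] * n
    if spec.charge_pattern == "alternating":
        return [spec.charge_magnitude * (1 if k % 2 == 0 else -1) for k in range(n)]
    raise SpecInvalid(f"unknown charge pattern {spec.charge_pattern!r}")


def _rotation(rng: np.random.Generator) -> np.ndarray:
    # QR of a random Gaussian matrix gives a Haar-ish rotation
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def build_ground_truth(spec: FixtureSpec) -> GroundTruth:
    """Lay out molecules and trajectories; all randomness from spec.seed."""
    tpl = spec.template
    n_per = len(tpl.elements)
    box_l = np.asarray(spec.box, dtype=float)
    max_bond = max(
        float(np.linalg.norm(tpl.coords[i] - tpl.coords[j]))
        for i, j in tpl.bonds
    ) if tpl.bonds else 0.0
    if max_bond >= box_l.min() / 2:
        raise SpecInvalid("bond length must be < half the shortest box side")

    rng = np.random.default_rng(spec.seed)
    charges_per = _charges_for(spec, n_per)

    elements: list[str] = []
    masses: list[float] = []
    charges: list[float] = []
    mols: list[int] = []
    bonds: list[tuple[int, int, int, int]] = []
    placements: list[np.ndarray] = []
    for m in range(spec.copies):
        offset = rng.uniform(0.0, box_l)
        placements.append(tpl.coords + offset)
        base = m * n_per
        for el in tpl.elements:
            elements.append(el)
            masses.append(_TYPE_MASSES[el])
        charges.extend(charges_per)
        mols.extend([m + 1] * n_per)
        for b, (i, j) in enumerate(tpl.bonds):
            bonds.append((len(bonds) + 1, 1, base + i + 1, base + j + 1))

    truth = GroundTruth(
        elements=elements,
        masses=masses,
        charges=charges,
        mols=mols,
        bonds=bonds,
        box=tuple((0.0, float(L)) for L in box_l),
    )
    current = [p.copy() for p in placements]
    for f in range(spec.frames):
        if spec.rigid_motion and f > 0:
            for m in range(spec.copies):
                rot = _rotation(rng)
                shift = rng.uniform(-2.0, 2.0, size=3)
                centroid = current[m].mean(axis=0)
                current[m] = (current[m] - centroid) @ rot.T + centroid + shift
        # Snap stored coordinates to a 2^-20 A grid: every coordinate and
        # every whole-box translation of it is then exactly representable,
        # so wrapping and unwrapping are lossless in floating point.
        truth.frames.append(
            {
                m + 1: np.round(current[m] * 2**20) / 2**20
                for m in range(spec.copies)
            }
        )
        truth.timesteps.append(f * 1000)
    return truth


def render_data_file(truth: GroundTruth) -> str:
    """Atom-style "full" data file text for the ground truth."""
    type_keys = sorted(set(truth.elements), key=lambda k: _TYPE_MASSES[k])
    type_of = {k: t + 1 for t, k in enumerate(type_keys)}
    lines = [
        "LAMMPS data file generated by lmp3d fixtures",
        "",
        f"{len(truth.elements)} atoms",
        f"{len(truth.bonds)} bonds",
        f"{len(type_keys)} atom types",
        f"{1 if truth.bonds else 0} bond types",
        "",
    ]
    for (lo, hi), ax in zip(truth.box, ("x", "y", "z")):
        lines.append(f"{lo:.6f} {hi:.6f} {ax}lo {ax}hi")
    lines += ["", "Masses", ""]
    for key in type_keys:
        lines.append(f"{type_of[key]} {_TYPE_MASSES[key]:.6f}  # {key}")
    lines += ["", "Atoms  # full", ""]
    frame0 = truth.frames[0]
    flat = np.concatenate([frame0[m] for m in sorted(frame0)])
    for k, (el, q, mol) in enumerate(
        zip(truth.elements, truth.charges, truth.mols)
    ):
        x, y, z = flat[k]
        lines.append(
            f"{k + 1} {mol} {type_of[el]} {q:.6f} "
            f"{float(x)!r} {float(y)!r} {float(z)!r}"
        )
    if truth.bonds:
        lines += ["", "Bonds", ""]
        for bid, bt, i, j in truth.bonds:
            lines.append(f"{bid} {bt} {i} {j}")
    lines.append("")
    return "\n".join(lines)


def render_dump(truth: GroundTruth, wrap: bool) -> str:
    """Text dump for all frames, wrapped (x y z) or unwrapped (xu yu zu)."""
    box_l = np.array([hi - lo for lo, hi in truth.box])
    box_lo = np.array([lo for lo, _ in truth.box])
    cols = "x y z" if wrap else "xu yu zu"
    lines: list[str] = []
    n_atoms = len(truth.elements)
    for f, frame in enumerate(truth.frames):
        flat = np.concatenate([frame[m] for m in sorted(frame)])
        if wrap:
            flat = box_lo + np.mod(flat - box_lo, box_l)
        lines += [
            "ITEM: TIMESTEP",
            str(truth.timesteps[f]),
            "ITEM: NUMBER OF ATOMS",
            str(n_atoms),
            "ITEM: BOX BOUNDS pp pp pp",
        ]
        for lo, hi in truth.box:
            lines.append(f"{lo:.6f} {hi:.6f}")
        lines.append(f"ITEM: ATOMS id mol type q {cols}")
        type_keys = sorted(set(truth.elements), key=lambda k: _TYPE_MASSES[k])
        type_of = {k: t + 1 for t, k in enumerate(type_keys)}
        for k in range(n_atoms):
            x, y, z = flat[k]
            lines.append(
                f"{k + 1} {truth.mols[k]} {type_of[truth.elements[k]]} "
                f"{truth.charges[k]:.6f} {float(x)!r} {float(y)!r} {float(z)!r}"
            )
    lines.append("")
    return "\n".join(lines)


def generate(spec: FixtureSpec) -> tuple[str, str, GroundTruth]:
    """Data-file text, dump text and the exact ground-truth record."""
    truth = build_ground_truth(spec)
    return render_data_file(truth), render_dump(truth, spec.wrap), truth


def write_fixture(spec: FixtureSpec, data_path, dump_path) -> GroundTruth:
    data_text, dump_text, truth = generate(spec)
    with open(data_path, "w") as fh:
        fh.write(data_text)
    with open(dump_path, "w") as fh:
        fh.write(dump_text)
    return truth


def perturb(coords: np.ndarray, seed: int) -> np.ndarray:
    """Seeded rigid rotation + translation, for invariance testing."""
    rng = np.random.default_rng(seed)
    rot = _rotation(rng)
    shift = rng.uniform(-5.0, 5.0, size=3)
    return coords @ rot.T + shift
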