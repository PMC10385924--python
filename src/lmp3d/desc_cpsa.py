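"""Set 4 — charged partial surface area (CPSA) descriptors.

A deterministic Shrake-Rupley-style solvent-accessible surface area (SASA)
engine distributes golden-spiral points on each atom's probe-expanded
sphere and keeps the points strictly outside every other expanded sphere.
The 30 CPSA descriptors then partition that surface by the sign and
magnitude of the atomic partial charges (Stanton-Jurs style PPSA/PNSA/
DPSA/FPSA/WPSA families plus charge-ratio and polar-surface terms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .molecular_model import MoleculeSnapshot

#: Solvent probe radius, A (water convention).
DEFAULT_PROBE = 1.4
#: Golden-spiral points per atomic sphere.
DEFAULT_POINTS = 960
#: |q| at or above this many e marks an atom as polar for TPSA/TASA.
POLAR_CHARGE_THRESHOLD = 0.2

NAMES = (
    "PPSA1", "PPSA2", "PPSA3",
    "PNSA1", "PNSA2", "PNSA3",
    "DPSA1", "DPSA2", "DPSA3",
    "FPSA1", "FPSA2", "FPSA3",
    "FNSA1", "FNSA2", "FNSA3",
    "WPSA1", "WPSA2", "WPSA3",
    "WNSA1", "WNSA2", "WNSA3",
    "RPCG", "RNCG", "RPCS", "RNCS",
    "TASA", "TPSA", "RASA", "RPSA",
    "SASA_total",
)


@dataclass
class SasaResult:
    areas: np.ndarray  # (N,) accessible area per atom, A^2
    total: float  # A^2
    n_points: int


def _golden_spiral(n: int) -> np.ndarray:
    """n deterministic, nearly uniform points on the unit sphere."""
    k = np.arange(n)
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = np.pi * (1.0 + 5.0**0.5) * k
    rho = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def sasa(
    snapshot: MoleculeSnapshot,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_POINTS,
) -> SasaResult:
    """Per-atom solvent-accessible surface areas.

    A surface point is accessible unless it lies strictly inside another
    atom's probe-expanded sphere, so two exactly coincident atoms each keep
    their full area.
    """
    radii = snapshot.topology.vdw_radii() + probe
    coords = snapshot.coords
    n = snapshot.n_atoms
    unit = _golden_spiral(n_points)
    tree = cKDTree(coords)
    areas = np.empty(n)
    r_max = radii.max()
    for i in range(n):
        pts = coords[i] + radii[i] * unit
        # only atoms whose expanded sphere can reach this one matter
        neighbours = [
            j
            for j in tree.query_ball_point(coords[i], radii[i] + r_max)
            if j != i
        ]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            # strict interiority occludes; the epsilon keeps points that lie
            # exactly on another sphere's boundary accessible despite rounding
            accessible &= d2 >= radii[j] ** 2 * (1.0 - 1e-12)
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * accessible.mean()
    return SasaResult(areas=areas, total=float(areas.sum()), n_points=n_points)


def cpsa(
    snapshot: MoleculeSnapshot,
    sasa_result: SasaResult | None = None,
    probe: float = DEFAULT_PROBE,
    n_points: int = DEFAULT_POINTS,
    polar_threshold: float = POLAR_CHARGE_THRESHOLD,
) -> dict[str, float]:
    """The 30 CPSA descriptors for one molecule-frame."""
    if sasa_result is None:
        sasa_result = sasa(snapshot, probe=probe, n_points=n_points)
    q = snapshot.topology.charges
    sa = sasa_result.areas
    tsa = sasa_result.total

    pos = q > 0
    neg = q < 0
    q_pos = float(q[pos].sum())
    q_neg = float(q[neg].sum())

    ppsa1 = float(sa[pos].sum())
    ppsa2 = q_pos * ppsa1
    ppsa3 = float((q[pos] * sa[pos]).sum())
    pnsa1 = float(sa[neg].sum())
    pnsa2 = q_neg * pnsa1
    pnsa3 = float((q[neg] * sa[neg]).sum())

    out: dict[str, float] = {
        "PPSA1": ppsa1, "PPSA2": ppsa2, "PPSA3": ppsa3,
        "PNSA1": pnsa1, "PNSA2": pnsa2, "PNSA3": pnsa3,
    }
    for k, (p, m) in enumerate(
        ((ppsa1, pnsa1), (ppsa2, pnsa2), (ppsa3, pnsa3)), start=1
    ):
        out[f"DPSA{k}"] = p - m
        out[f"FPSA{k}"] = p / tsa if tsa > 0 else 0.0
        out[f"FNSA{k}"] = m / tsa if tsa > 0 else 0.0
        out[f"WPSA{k}"] = p * tsa / 1000.0
        out[f"WNSA{k}"] = m * tsa / 1000.0

    if pos.any():
        rpcg = float(q[pos].max()) / q_pos
        rpcs = float(sa[np.flatnonzero(pos)[np.argmax(q[pos])]]) * rpcg
    else:
        rpcg = rpcs = 0.0
    if neg.any():
        rncg = abs(float(q.min())) / abs(q_neg)
        rncs = float(sa[np.argmin(q)]) * rncg
    else:
        rncg = rncs = 0.0
    out.update({"RPCG": rpcg, "RNCG": rncg, "RPCS": rpcs, "RNCS": rncs})

    polar = np.abs(q) >= polar_threshold
    tpsa = float(sa[polar].sum())
    out["TPSA"] = tpsa
    out["TASA"] = tsa - tpsa
    out["RPSA"] = tpsa / tsa if tsa > 0 else 0.0
    out["RASA"] = (tsa - tpsa) / tsa if tsa > 0 else 0.0
    out["SASA_total"] = tsa
    return {name: out[name] for name in NAMES}
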