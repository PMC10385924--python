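"""Set 3 — GETAWAY descriptors (GEometry, Topology, and Atom-Weights
AssemblY).

Built on the molecular influence matrix H = M (M^T M)^+ M^T of the
centered coordinates M: its diagonal (the atomic leverages) measures each
atom's influence on the molecular geometry, and the influence/distance
matrix R combines leverages with interatomic distances.  Scalar information
indices (ITH, ISH, HIC, HGM, RARS, RCON, REIG) are complemented by
topology-lagged autocorrelation vectors H_k, HATS_k, R_k and Rmax_k for
eight atomic weighting schemes, lags 0..8 (H/HATS) and 1..8 (R/Rmax).
"""

from __future__ import annotations

import numpy as np

from .molecular_model import MoleculeSnapshot

SCHEMES = ("u", "m", "c", "v", "e", "p", "i", "a")
MAX_LAG = 8
#: Leverage values closer than this are one symmetry-equivalence class.
LEVERAGE_TOL = 1e-6


def influence_matrix(centered: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Molecular influence matrix and its diagonal (leverages).

    Uses the Moore-Penrose pseudo-inverse so planar/linear (rank-deficient)
    geometries are handled; H is then the orthogonal projector onto the
    column space of the centered coordinates.
    """
    m = np.asarray(centered, dtype=float).reshape(-1, 3)
    h = m @ np.linalg.pinv(m.T @ m) @ m.T
    return h, np.diag(h).copy()


def _names_for_scheme(w: str) -> list[str]:
    names = [f"H{k}{w}" for k in range(MAX_LAG + 1)]
    names.append(f"HT{w}")
    names += [f"HATS{k}{w}" for k in range(MAX_LAG + 1)]
    names.append(f"HATST{w}")
    names += [f"R{k}{w}" for k in range(1, MAX_LAG + 1)]
    names.append(f"RT{w}")
    names += [f"Rmax{k}{w}" for k in range(1, MAX_LAG + 1)]
    names.append(f"RmaxT{w}")
    return names


NAMES = tuple(
    ["ITH", "ISH", "HIC", "HGM", "RARS", "RCON", "REIG"]
    + [n for w in SCHEMES for n in _names_for_scheme(w)]
)


def getaway(snapshot: MoleculeSnapshot) -> dict[str, float]:
    """All 311 GETAWAY descriptors for one molecule-frame."""
    topo = snapshot.topology
    n = snapshot.n_atoms
    h_mat, lev = influence_matrix(snapshot.centered)
    d_top = topo.topo_dist
    dist = snapshot.distances

    # --- scalar indices -------------------------------------------------
    # ITH/ISH: information content of leverage equality classes
    classes: list[list[int]] = []
    for i in range(n):
        for cls in classes:
            if abs(lev[cls[0]] - lev[i]) <= LEVERAGE_TOL:
                cls.append(i)
                break
        else:
            classes.append([i])
    ith = n * np.log2(n) - sum(len(c) * np.log2(len(c)) for c in classes) if n > 1 else 0.0
    ish = ith / (n * np.log2(n)) if n > 1 else 0.0

    total_lev = lev.sum()
    pos = lev[lev > 0]
    if total_lev > 0 and len(pos):
        p = pos / total_lev
        hic = float(-(p * np.log2(p)).sum())
        hgm = 100.0 * float(np.exp(np.log(pos).sum() / n))
    else:
        hic = 0.0
        hgm = 0.0

    # influence/distance matrix R
    r_mat = np.zeros((n, n))
    if n > 1:
        iu, ju = np.triu_indices(n, 1)
        vals = np.sqrt(lev[iu] * lev[ju]) / dist[iu, ju]
        r_mat[iu, ju] = vals
        r_mat[ju, iu] = vals
    row_sums = r_mat.sum(axis=1)
    rars = float(row_sums.sum() / n) if n else 0.0
    bonds = topo.bonds
    rcon = (
        float(np.sqrt(row_sums[bonds[:, 0]] * row_sums[bonds[:, 1]]).sum())
        if len(bonds)
        else 0.0
    )
    reig = float(np.linalg.eigvalsh(r_mat)[-1]) if n > 1 else 0.0

    out: dict[str, float] = {
        "ITH": float(ith),
        "ISH": float(ish),
        "HIC": hic,
        "HGM": hgm,
        "RARS": rars,
        "RCON": rcon,
        "REIG": reig,
    }

    # --- lagged, weighted vectors ---------------------------------------
    iu, ju = np.triu_indices(n, 1)
    lag = d_top[iu, ju] if n > 1 else np.array([], dtype=int)
    h_off = h_mat[iu, ju] if n > 1 else np.array([])
    r_off = r_mat[iu, ju] if n > 1 else np.array([])
    for w in SCHEMES:
        wt = topo.weights(w)
        ww = wt[iu] * wt[ju] if n > 1 else np.array([])
        hw = lev * wt
        hats_pair = hw[iu] * hw[ju] if n > 1 else np.array([])
        for k in range(MAX_LAG + 1):
            if k == 0:
                out[f"H{k}{w}"] = float((lev * wt**2).sum())
                out[f"HATS{k}{w}"] = float((hw**2).sum())
                continue
            at_lag = lag == k
            out[f"H{k}{w}"] = float(
                (h_off[at_lag & (h_off > 0)] * ww[at_lag & (h_off > 0)]).sum()
            )
            out[f"HATS{k}{w}"] = float(hats_pair[at_lag].sum())
            r_terms = r_off[at_lag] * ww[at_lag]
            out[f"R{k}{w}"] = float(r_terms.sum())
            out[f"Rmax{k}{w}"] = float(r_terms.max()) if len(r_terms) else 0.0
        out[f"HT{w}"] = float(sum(out[f"H{k}{w}"] for k in range(MAX_LAG + 1)))
        out[f"HATST{w}"] = float(
            sum(out[f"HATS{k}{w}"] for k in range(MAX_LAG + 1))
        )
        out[f"RT{w}"] = float(sum(out[f"R{k}{w}"] for k in range(1, MAX_LAG + 1)))
        out[f"RmaxT{w}"] = float(
            sum(out[f"Rmax{k}{w}"] for k in range(1, MAX_LAG + 1))
        )
    return {name: out[name] for name in NAMES}
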