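"""Set 5 — WHIM (Weighted Holistic Invariant Molecular) descriptors.

Each weighting scheme builds a weighted covariance matrix of the atomic
coordinates; its eigenvalues and score projections yield directional size
(lam1-3), shape (th1, th2), symmetry (gam1-3) and atom-density (e1-3)
statistics plus five global aggregates (T, A, V, K, G).  Seven schemes
(unit, mass, |charge|, vdW volume, electronegativity, polarizability,
ionization potential) give 16 x 7 = 112 descriptors.
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateWeights
from .molecular_model import MoleculeSnapshot

SCHEMES = ("u", "m", "c", "v", "e", "p", "i")
#: An atom whose score is within this window of the negated score of another
#: atom of the same element counts as its mirror counterpart, A.
SYMMETRY_TOL = 0.5
#: |score| below this makes an atom its own counterpart (on the plane), A.
SELF_TOL = 0.25

_DIRECTIONAL = ("L1", "L2", "L3", "Th1", "Th2", "G1", "G2", "G3", "E1", "E2", "E3")
_GLOBAL = ("T", "A", "V", "K", "G")

NAMES = tuple(f"{base}{w}" for w in SCHEMES for base in _DIRECTIONAL + _GLOBAL)


def _fix_eigenvector_signs(vecs: np.ndarray) -> np.ndarray:
    """Make each eigenvector's largest-magnitude component positive so score
    signs are deterministic."""
    out = vecs.copy()
    for k in range(out.shape[1]):
        idx = np.argmax(np.abs(out[:, k]))
        if out[idx, k] < 0:
            out[:, k] = -out[:, k]
    return out


def whim_scheme(snapshot: MoleculeSnapshot, scheme: str) -> dict[str, float]:
    """The 16 WHIM values for one weighting scheme.

    The charge scheme uses |q|; a molecule whose charges are all zero falls
    back to unit weights for that scheme.  A non-charge scheme whose weights
    sum to zero raises :class:`DegenerateWeights`.
    """
    if scheme == "c":
        w = np.abs(snapshot.topology.charges)
        if w.sum() == 0:
            w = np.ones(snapshot.n_atoms)
    else:
        w = snapshot.topology.weights(scheme)
        if w.sum() <= 0:
            raise DegenerateWeights(f"scheme {scheme!r} has zero total weight")

    coords = snapshot.coords
    n = snapshot.n_atoms
    mean = (w[:, None] * coords).sum(axis=0) / w.sum()
    d = coords - mean
    cov = (w[:, None, None] * d[:, :, None] * d[:, None, :]).sum(axis=0) / w.sum()
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    lam = np.clip(eigvals[order], 0.0, None)
    vecs = _fix_eigenvector_signs(eigvecs[:, order])
    scores = d @ vecs  # t_im

    t = float(lam.sum())
    th = [float(lam[m] / t) if t > 0 else 0.0 for m in range(2)]

    gam = []
    elements = snapshot.topology.elements
    for m in range(3):
        tm = scores[:, m]
        matched = 0
        for i in range(n):
            if abs(tm[i]) < SELF_TOL:
                matched += 1
                continue
            for j in range(n):
                if j == i or elements[j] != elements[i]:
                    continue
                if abs(tm[j] - (-tm[i])) <= SYMMETRY_TOL:
                    matched += 1
                    break
        gam.append(matched / n if n else 0.0)

    e = []
    for m in range(3):
        t4 = float((scores[:, m] ** 4).sum())
        e.append(float(lam[m] ** 2 * n / t4) if lam[m] > 0 and t4 > 0 else 0.0)

    a = float(lam[0] * lam[1] + lam[0] * lam[2] + lam[1] * lam[2])
    v = t + a + float(lam[0] * lam[1] * lam[2])
    k = float(np.abs(lam / t - 1.0 / 3.0).sum() / (4.0 / 3.0)) if t > 0 else 0.0
    g = float((gam[0] * gam[1] * gam[2]) ** (1.0 / 3.0))

    vals = list(lam) + th + gam + e + [t, a, v, k, g]
    return {
        f"{base}{scheme}": float(val)
        for base, val in zip(_DIRECTIONAL + _GLOBAL, vals)
    }


def whim(snapshot: MoleculeSnapshot) -> dict[str, float]:
    """All 112 WHIM descriptors (16 values x 7 weighting schemes)."""
    out: dict[str, float] = {}
    for scheme in SCHEMES:
        out.update(whim_scheme(snapshot, scheme))
    return {name: out[name] for name in NAMES}
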