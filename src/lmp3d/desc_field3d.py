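"""Set 6 — distance-spectrum descriptors: 3D RDF, 3D-MoRSE, and the
Moreau-Broto (ATS), Moran and Geary 3D spatial autocorrelations.

RDF and MoRSE use pair weights under eight schemes (unit + seven atomic
properties); the autocorrelations use the seven centered properties only,
over 1 A distance-lag bins, giving 240 + 240 + 3 x 210 = 1110 values.
"""

from __future__ import annotations

import numpy as np

from .molecular_model import MoleculeSnapshot

#: Gaussian smoothing parameter of the RDF, 1/A^2.
RDF_BETA = 100.0
#: RDF is sampled at r = 0.5, 1.0, ..., 15.0 A (30 radii).
RDF_RADII = np.arange(1, 31) * 0.5
#: MoRSE scattering parameter s = 0..29 1/A.
MORSE_S = np.arange(30, dtype=float)
#: Autocorrelation lag bins [k, k+1) A, k = 0..29.
N_BINS = 30

PAIR_SCHEMES = ("u", "m", "c", "v", "e", "p", "i", "a")
AC_SCHEMES = ("c", "m", "v", "e", "p", "i", "a")

RDF_NAMES = tuple(
    f"RDF{int(round(r * 10)):03d}{w}" for w in PAIR_SCHEMES for r in RDF_RADII
)
MORSE_NAMES = tuple(
    f"Mor{k + 1:02d}{w}" for w in PAIR_SCHEMES for k in range(30)
)
ATS_NAMES = tuple(f"ATS{k}{w}" for w in AC_SCHEMES for k in range(N_BINS))
MATS_NAMES = tuple(f"MATS{k}{w}" for w in AC_SCHEMES for k in range(N_BINS))
GATS_NAMES = tuple(f"GATS{k}{w}" for w in AC_SCHEMES for k in range(N_BINS))

NAMES = RDF_NAMES + MORSE_NAMES + ATS_NAMES + MATS_NAMES + GATS_NAMES


def _pairs(snapshot: MoleculeSnapshot):
    n = snapshot.n_atoms
    iu, ju = np.triu_indices(n, 1)
    return iu, ju, snapshot.distances[iu, ju]


def rdf(snapshot: MoleculeSnapshot, scheme: str) -> np.ndarray:
    """Property-weighted radial distribution sampled at 30 radii."""
    if snapshot.n_atoms < 2:
        return np.zeros(30)
    iu, ju, r = _pairs(snapshot)
    w = snapshot.topology.weights(scheme)
    ww = w[iu] * w[ju]
    return np.array(
        [float((ww * np.exp(-RDF_BETA * (rk - r) ** 2)).sum()) for rk in RDF_RADII]
    )


def morse(snapshot: MoleculeSnapshot, scheme: str) -> np.ndarray:
    """3D-MoRSE scattering code I(s) = sum w_i w_j sin(s r)/(s r)."""
    if snapshot.n_atoms < 2:
        return np.zeros(30)
    iu, ju, r = _pairs(snapshot)
    w = snapshot.topology.weights(scheme)
    ww = w[iu] * w[ju]
    out = np.empty(30)
    for k, s in enumerate(MORSE_S):
        x = s * r
        sinc = np.where(x == 0, 1.0, np.sin(x) / np.where(x == 0, 1.0, x))
        out[k] = float((ww * sinc).sum())
    return out


def autocorrelations(
    snapshot: MoleculeSnapshot, scheme: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Moreau-Broto (ATS), Moran and Geary vectors over 1 A lag bins."""
    n = snapshot.n_atoms
    ats = np.zeros(N_BINS)
    moran = np.zeros(N_BINS)
    geary = np.zeros(N_BINS)
    if n < 2:
        return ats, moran, geary
    iu, ju, r = _pairs(snapshot)
    w = snapshot.topology.weights(scheme)
    wbar = w.mean()
    s2 = float(((w - wbar) ** 2).sum())
    bins = np.floor(r).astype(int)
    for k in range(N_BINS):
        sel = bins == k
        delta = int(sel.sum())
        if delta == 0:
            continue
        wi, wj = w[iu[sel]], w[ju[sel]]
        ats[k] = float((wi * wj).sum())
        if s2 > 0:
            moran[k] = (
                float(((wi - wbar) * (wj - wbar)).sum()) / delta
            ) / (s2 / n)
            geary[k] = (float(((wi - wj) ** 2).sum()) / (2 * delta)) / (
                s2 / (n - 1)
            )
    return ats, moran, geary


def field3d(snapshot: MoleculeSnapshot) -> dict[str, float]:
    """All 1110 set-6 descriptors in stable column order."""
    out: dict[str, float] = {}
    for w in PAIR_SCHEMES:
        for rk, val in zip(RDF_RADII, rdf(snapshot, w)):
            out[f"RDF{int(round(rk * 10)):03d}{w}"] = float(val)
    for w in PAIR_SCHEMES:
        for k, val in enumerate(morse(snapshot, w)):
            out[f"Mor{k + 1:02d}{w}"] = float(val)
    acc = {w: autocorrelations(snapshot, w) for w in AC_SCHEMES}
    for prefix, idx in (("ATS", 0), ("MATS", 1), ("GATS", 2)):
        for w in AC_SCHEMES:
            for k in range(N_BINS):
                out[f"{prefix}{k}{w}"] = float(acc[w][idx][k])
    return {name: out[name] for name in NAMES}
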