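"""Compute a handful of descriptors for one molecule at one frame.

Unwraps a wrapped trajectory, builds the molecule snapshot and prints the
QSPR features highlighted for hydrocarbon property prediction: HGM (the
geometric mean of the GETAWAY leverages, x100), the Kuhn length lk, the
van der Waals molecular volume, and the folding profile phi4 — plus the
radius of gyration for orientation.
"""

import tempfile
from pathlib import Path

from lmp3d import build_topology, make_snapshot, parse_data, parse_dump, unwrap_frame
from lmp3d.desc_geometric import chain_measures, inertia_and_gyration, molvolume
from lmp3d.desc_getaway import getaway
from lmp3d.fixtures import FixtureSpec, random_walk_chain, write_fixture

workdir = Path(tempfile.mkdtemp())
spec = FixtureSpec(
    template=random_walk_chain(16, 1.54, seed=4),
    box=(25.0, 25.0, 25.0),
    wrap=True,
    seed=4,
)
write_fixture(spec, workdir / "c16.data", workdir / "c16.lammpstrj")

topo = build_topology(parse_data(workdir / "c16.data"))
frame = parse_dump(workdir / "c16.lammpstrj")[0]
coords = unwrap_frame(frame, topo)[1]
snap = make_snapshot(topo.molecules[1], frame.timestep, coords)

chain = chain_measures(snap)
print(f"HGM       = {getaway(snap)['HGM']:.4f}   (higher -> more even atom influence)")
print(f"lk        = {chain['lk']:.4f} A (Kuhn length: Ree^2 / contour length)")
print(f"molvolume = {molvolume(snap):.2f} A^3 (union of vdW spheres)")
print(f"phi4      = {chain['phi4']:.4f}   (4-bond backbone straightness, 1 = straight)")
print(f"Rg        = {inertia_and_gyration(snap)['Rg']:.4f} A")
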